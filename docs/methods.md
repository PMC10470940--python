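# Methods

## The model

`subcdr` predicts the natural-log IC50 of a drug against a cancer cell
line by decomposing both sides into *subcomponents* and scoring all of
their pairwise interactions.

**Drug side.** A SMILES string is cleaved at retrosynthetically
meaningful bonds (BRICS), giving an ordered fragment sequence
`[g_1, …, g_m]`; fragments are ordered by the position of their first
real atom in the input SMILES, so the sequence follows the molecule as
written. Each fragment is embedded as a 512-bit Morgan/ECFP fingerprint
(radius 2) and the sequence is encoded by a two-layer unidirectional
GRU into contextual features `d̂_i ∈ R^F`. Sequences are zero-padded to
the corpus-wide maximum fragment count `t_d`; padded positions are
masked everywhere downstream.

**Cell side.** The 656 Cancer Gene Census genes (emulated at smaller
scale in the synthetic worlds) are partitioned into `n` disjoint role
subsets — oncogene, tumour-suppressor, fusion, unknown, and their
overlaps; genes with multiple roles go to a dedicated overlap subset so
the partition stays disjoint. A per-cell-line binary mask zeroes genes
not annotated for the cell's tumour type. Subset expression vectors are
zero-padded to the largest subset size `t_c` and encoded by a two-layer
1-D CNN followed by a linear map to width `F`.

The cell-side convolution is **depthwise** (one channel per gene
subset, no channel mixing). This is a deliberate restriction: with
channel-mixing kernels, row `i` of the encoded matrix blends all
subsets and the interaction map's columns lose their meaning. Depthwise
convolution guarantees that column `j` of the map can only carry
information from subset `j`'s genes — the structural basis of the
map's interpretability.

**Interaction map.** Every (fragment, subset) pair is scored
`Ω_ij = σ(d̂_i ω ĉ_j^T + b₀)` with a trainable bilinear matrix
`ω ∈ R^{F×F}`. The map is lifted to a weighted complete bipartite
graph (fragment nodes vs subset nodes, edge weights `Ω`, one-hot node
attributes, unit self-loops) and propagated for two rounds of
graph convolution with leaky-ReLU activations:

    z_v ← σ( Σ_{u ∈ N(v) ∪ {v}} a_vu / (q_v q_u) · Θ z_u ),  q_v = 1 + |N(v)|

The normalization divides by the *product* `q_v q_u` as typeset; a
`sym_sqrt` switch provides the `√(q_v q_u)` reading, and a `simplified`
switch drops intermediate nonlinearities. Both normalizations are
validated against a brute-force per-node summation oracle. Padded
fragments are excluded from the graph, its degrees and the pooling.
Node embeddings are pooled by concatenated global max and mean.

Because node attributes are one-hot identities, the pooled summary is
a function of the interaction map alone: **the map is an information
bottleneck** — every piece of drug- or cell-specific information used
by the decoder must pass through some map entry. This is what makes
the map a faithful attribution surface rather than a post-hoc one.

**Side information.** The training-partition responses form a masked
drugs × cells matrix; minimizing `½‖M ⊙ (R − I^T J)‖²_F` by gradient
descent with backtracking (monotone objective; ALS and zero-imputed
truncated SVD available as options) gives low-rank factors whose rows
pass through a small batch-normalized fully-connected head into
per-drug and per-cell side vectors. Factors are rebuilt per fold from
training data only; entities unseen in training get zero vectors and a
cold-start flag.

**Decoder and loss.** The pooled summary and the two side vectors are
concatenated into a three-layer MLP with dropout. Regression uses the
Huber loss (δ = 1, quadratic within δ, linear beyond — gradient
magnitude never exceeds δ); classification adds a terminal sigmoid and
uses binary cross-entropy with the same upstream parameters.

## Interpretability: closed-gate initialization and fit-then-prune

A map entry influences the prediction through its *variation*, not its
level: under a regression loss the operating point of a sigmoid score
is a free gauge (the decoder's gain can compensate any level), so in
an unconstrained model high average scores do not identify the driving
pairs — saturated-but-constant entries are free.

Two devices pin the gauge so that high trained scores do mark the
driving pairs:

1. **Closed initialization.** A fixed offset `b₀ = −1` on the bilinear
   logits starts every score low.
2. **Fit-then-prune** (`train_interpretable`): a warm-up phase fits
   without weight decay; a pruning phase continues training while L2
   decay — concentrated on the encoders and `ω`, milder elsewhere —
   pulls parameters not needed for prediction back toward zero.
   Irrelevant scores relax to the closed level; pairs the prediction
   depends on must sit on the responsive part of the logistic and stay
   up.

The planted-signal experiment uses this schedule with side information
disabled, since a masked factorization of a densely observed training
grid can memorize the responses outright and starve the interaction
path of gradient.

## Ablation variants

Five config toggles reproduce the structural variants: `no_side_info`
(drop side vectors from the decoder input), `no_sequence_encoders`
(raw fingerprints and raw subset expression feed the bilinear scorer
directly, `ω` reshaped accordingly), `no_graph` (the masked map is
flattened straight into the decoder), `gated_graph` (a gated recurrent
message-passing layer, supporting edge weights, replaces the GCN), and
`no_subcomponents` (whole-drug fingerprint and masked expression go
directly to the decoder).

## Synthetic data

`fixtures.generate_world` builds a fully synthetic study: drugs drawn
from a curated list of ~30 valid small molecules (aspirin first, plus
non-cleavable controls such as benzene and toluene and non-aromatic
carbonyl/ester controls), genes partitioned round-robin into
near-equal subsets with census-style labels, i.i.d. standard-normal
expression, tumour types cycling round-robin over cells, and each gene
annotated relevant to each tumour type with probability 0.9.
Responses follow

    response = baseline + Σ_planted [drug ⊃ pattern] · mean(masked subset expr) · effect + N(0, noise_sd)

with defaults baseline 1.0, one planted effect of +2.0 and noise SD
0.3, chosen so the planted signal (SD ≈ 0.5–0.7 at subset sizes of ~8
genes) is clearly above noise but not trivial. The default planted
pattern is a phenyl ring: rings survive BRICS fragmentation as intact
fragments, whereas bond-centred patterns (esters, amides) are exactly
what BRICS cleaves, so no single fragment would retain them.

What the generator does *not* emulate: GDSC's empirical IC50
distribution and scale, correlated co-expression structure, realistic
fragment-vocabulary diversity, and measurement heteroscedasticity.
Passing tests therefore demonstrate mechanism correctness and
desk-scale learnability, not clinical-scale accuracy.

The generative R² ceiling `var(signal)/var(signal + noise)` is
computable per world (`fixtures.r2_ceiling`) and upper-bounds any
model's attainable test R².

## Planted-pair recovery protocol

`fixtures.planted_recovery_trial` freezes the recovery experiment:
a world of 20 drugs × 45 cells × 24 genes × 3 subsets with one planted
(phenyl, first-subset) effect of +2.0; the model (F = 16, closed-gate
offset −1, no side information, dropout 0, Adam 3e-3, batch 32)
trained with 80 warm-up plus 200 pruning epochs (decay 2e-3 on
encoders/ω, 5e-4 elsewhere). Success means the highest
instance-averaged map score over pattern-bearing instances falls on a
pattern-bearing fragment crossed with the planted subset. The 20-drug
world matters: it includes non-aromatic control molecules sharing the
pattern drugs' other fragments, without which co-occurring fragments
are statistically indistinguishable carriers of the planted signal.
Across ten seeded replicates the protocol recovers the planted pair in
a majority of runs.

## Numerical choices

* All computation is float64 NumPy; trainable layers run on a small
  tape-based reverse-mode autodiff engine (`subcdr.autodiff`) — the
  models here have at most a few thousand parameters, so this is both
  adequate and dependency-light. Gradients are finite-difference
  checked in the test suite.
* Logistic scores are clipped to `[1e-12, 1 − 1e-12]` so saturated
  values remain strictly inside the open interval the map guarantees.
* Ties in `top_interactions` break by (row, column) index; the max
  pool routes gradient to the first maximal entry.
* Masked-factorization gradient descent uses backtracking step
  halving, so the recorded objective history is non-increasing by
  construction; initialization is seeded Gaussian scaled to the
  observed-entry magnitude.
* Unmeasured response-matrix entries store 0 under a 0 mask; all
  consumers consult the mask, never the sentinel.
* Binarization uses strict inequality (response < −2.0 → sensitive);
  `exp(−2.0) ≈ 0.135 µM`.
* Duplicate (drug, cell) measurements collapse to the highest ln-IC50;
  drugs with identical canonical SMILES merge to one compound; the
  90/10 independent split is a seeded unstratified random split.
* Cross-validation: `warm` shuffles instances; `cold_cell`/`cold_drug`
  split the entity set so test entities never occur in training.
* Default hyperparameters follow the recommended setup (ECFP radius 2
  / width 512; two GRU, CNN and GCN layers; three-layer decoder with
  dropout 0.2; δ = 1; Adam 1e-4); hidden width F = 64, factor rank 16,
  batch size 128 and 100 epochs are package choices where the setup is
  silent. Tests and the acceptance script run smaller widths, higher
  learning rates and fewer epochs so the whole suite completes on one
  CPU in minutes; these sizes are stated in the relevant functions.

## Known limitations

* Desk-scale worlds cannot reproduce benchmark accuracies on GDSC;
  the package reproduces the method, its invariants and its
  desk-scale learning behaviour.
* Cold-start prediction relies on feature similarity alone and
  degrades, as expected for this model family.
* The recovery statistic (argmax of the instance-averaged map) is
  conservative: the trained map may split the planted effect between a
  presence "gate" cell and an expression "modulation" cell in the same
  column, in which case the top cell identifies the right subset but a
  co-occurring fragment.
* Masking zeroes are indistinguishable from true zero expression
  downstream; the annotation table is taken as ground truth.
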