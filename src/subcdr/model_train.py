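"""End-to-end drug-response model: encoders, interaction graph, decoder.

The full forward pass runs fragment sequences through the GRU encoder
and gene-subset profiles through the CNN encoder, scores all
subcomponent pairs into the interaction map, propagates over the
weighted complete bipartite graph with a GCN, pools to a summary
vector, concatenates side-information rows and decodes with an MLP into
a predicted ln-IC50 (regression) or sensitivity probability
(classification). Training minimizes the Huber loss (regression) or
binary cross-entropy (classification) with Adam.

Five ablation variants are exposed as config toggles: ``no_side_info``,
``no_sequence_encoders`` (raw fingerprints/expression feed the bilinear
scorer), ``no_graph`` (the map is flattened straight into the decoder),
``gated_graph`` (a gated recurrent message-passing layer replaces the
GCN) and ``no_subcomponents`` (whole-drug fingerprint and expression
profile go directly to the decoder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .autodiff import Tensor, Adam, concat
from .nn import Linear, MLP, batch_norm, glorot
from .drug_subcomponents import build_sequence, brics_decompose
from .cell_subcomponents import GeneCatalog, build_profile
from .interaction import InteractionMap
from .data_io import build_response_matrix, CDRInstance
from .side_info import factorize

__all__ = [
    "ModelConfig", "MetricsReport", "CDRDataset", "SubCDRModel",
    "huber_loss", "train", "evaluate", "decode",
]

_ABLATIONS = {"no_side_info", "no_sequence_encoders", "no_graph",
              "gated_graph", "no_subcomponents"}


@dataclass
class ModelConfig:
    hidden: int = 64                   # latent width F shared by both encoders
    gru_layers: int = 2
    cnn_layers: int = 2
    cnn_kernel: int = 3
    gcn_layers: int = 2
    gcn_norm: str = "product"          # or "sym_sqrt"
    gcn_simplified: bool = False
    #: fixed offset on the bilinear interaction logits. A negative value
    #: starts all interaction scores low ("closed"), so that under the
    #: fit-then-prune schedule (``train_interpretable``) only
    #: subcomponent pairs that must transmit signal climb into the
    #: responsive part of the logistic and high trained scores mark the
    #: pairs that drive the prediction.
    interaction_bias: float = -1.0
    #: uniform L2 weight decay applied during ``train`` (0 = none).
    weight_decay: float = 0.0
    decoder_hidden: tuple = (64, 32)   # 3-layer MLP: two hidden + output
    dropout: float = 0.2
    huber_delta: float = 1.0
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 128
    task: str = "regression"           # or "classification"
    ablation: frozenset = frozenset()
    side_rank: int = 16
    side_width: int = 16
    side_iters: int = 300
    fp_radius: int = 2
    fp_width: int = 512
    seed: int = 0

    def __post_init__(self):
        if self.huber_delta <= 0:
            raise ValueError("huber delta must be > 0")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.gcn_layers < 1:
            raise ValueError("GCN needs at least one layer")
        self.ablation = frozenset(self.ablation)
        unknown = self.ablation - _ABLATIONS
        if unknown:
            raise ValueError(f"unknown ablation toggles {sorted(unknown)}")

    def to_dict(self):
        d = asdict(self)
        d["ablation"] = sorted(self.ablation)
        d["decoder_hidden"] = list(self.decoder_hidden)
        return d

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ablation" in raw:
            raw["ablation"] = frozenset(raw["ablation"])
        if "decoder_hidden" in raw:
            raw["decoder_hidden"] = tuple(raw["decoder_hidden"])
        return cls(**raw)


@dataclass
class MetricsReport:
    rmse: Optional[float] = None
    pcc: Optional[float] = None
    r2: Optional[float] = None
    auc: Optional[float] = None
    aupr: Optional[float] = None
    n: int = 0
    undefined: bool = False            # single-class AUC etc.
    per_group: dict = field(default_factory=dict)


class CDRDataset:
    """Precomputed per-drug / per-cell features plus instance arrays."""

    def __init__(self, instances, smiles_by_drug: dict, expression: pd.DataFrame,
                 catalog: GeneCatalog, tumour_type_of: dict,
                 fp_radius: int = 2, fp_width: int = 512,
                 strict_mask: bool = True, t_d: int = None):
        from .drug_subcomponents import embed_fragments

        self.drug_index = sorted(smiles_by_drug)
        self.cell_index = [str(c) for c in expression.index]
        self.catalog = catalog
        self.smiles_by_drug = dict(smiles_by_drug)

        frag_lists = {d: brics_decompose(smiles_by_drug[d])
                      for d in self.drug_index}
        self.t_d = t_d or max(len(f) for f in frag_lists.values())
        seqs = [build_sequence(d, smiles_by_drug[d], self.t_d,
                               radius=fp_radius, width=fp_width)
                for d in self.drug_index]
        self.sequences = {s.drug_id: s for s in seqs}
        self.drug_feat = np.stack([s.features for s in seqs])
        self.drug_mask = np.stack([s.pad_mask for s in seqs])
        self.whole_fp = np.stack([
            embed_fragments([smiles_by_drug[d]], radius=fp_radius,
                            width=fp_width)[0]
            for d in self.drug_index])

        profiles = [build_profile(c, expression.loc[c], tumour_type_of[c],
                                  catalog, strict=strict_mask)
                    for c in self.cell_index]
        self.profiles = {p.cell_id: p for p in profiles}
        self.cell_feat = np.stack([p.subsets for p in profiles])
        self.masked_expr = np.stack([
            expression.loc[c].to_numpy(dtype=float) * p.mask_applied
            for c, p in zip(self.cell_index, profiles)])

        self._dpos = {d: i for i, d in enumerate(self.drug_index)}
        self._cpos = {c: j for j, c in enumerate(self.cell_index)}
        self.instances = list(instances)
        self.di = np.array([self._dpos[x.drug_id] for x in instances], dtype=int)
        self.ci = np.array([self._cpos[x.cell_id] for x in instances], dtype=int)
        self.y = np.array([x.response for x in instances])
        self.labels = np.array([x.label if x.label is not None else -1
                                for x in instances])

    @property
    def n_subsets(self):
        return self.cell_feat.shape[1]

    @property
    def t_c(self):
        return self.cell_feat.shape[2]

    def __len__(self):
        return len(self.instances)


def huber_loss(pred, true, delta: float = 1.0):
    """Mean Huber loss: quadratic within delta of zero error, linear beyond.

    Accepts NumPy arrays (returns a float) or autodiff Tensors (returns
    a scalar Tensor for backprop).
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    if isinstance(pred, Tensor) or isinstance(true, Tensor):
        pred = pred if isinstance(pred, Tensor) else Tensor(pred)
        true = true if isinstance(true, Tensor) else Tensor(true)
        e = pred - true
        quad = np.abs(e.data) <= delta
        m = Tensor(quad.astype(np.float64))
        per = m * (e ** 2.0) * 0.5 + (1.0 - m) * (e.abs() * delta - 0.5 * delta ** 2)
        return per.mean()
    e = np.asarray(pred, dtype=float) - np.asarray(true, dtype=float)
    per = np.where(np.abs(e) <= delta, 0.5 * e ** 2,
                   delta * np.abs(e) - 0.5 * delta ** 2)
    return float(per.mean())


def _bce_loss(pred: Tensor, true: np.ndarray, eps: float = 1e-12):
    y = Tensor(np.asarray(true, dtype=float))
    return -(y * (pred + eps).log()
             + (1.0 - y) * (1.0 - pred + eps).log()).mean()


def decode(h, i_hat, j_hat, decoder: MLP, task: str = "regression",
           rng=None, train: bool = False):
    """Decoder head: MLP over [h || i_hat || j_hat] (side rows optional)."""
    parts = [x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
             for x in (h, i_hat, j_hat) if x is not None]
    z = concat(parts, axis=-1) if len(parts) > 1 else parts[0]
    out = decoder(z, rng=rng, train=train)
    out = out.reshape(out.shape[0]) if out.ndim == 2 else out
    if task == "classification":
        out = out.sigmoid()
    return out


class SubCDRModel:
    """Trainable subcomponent-interaction response model."""

    def __init__(self, dataset: CDRDataset, config: ModelConfig,
                 train_idx=None):
        self.ds = dataset
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        rng = self.rng
        F = config.hidden
        ab = config.ablation
        t_d, n_sub, t_c = dataset.t_d, dataset.n_subsets, dataset.t_c

        if "no_subcomponents" not in ab:
            if "no_sequence_encoders" in ab:
                d_width, c_width = config.fp_width, t_c
                self.drug_enc = self.cell_enc = None
            else:
                from .drug_subcomponents import DrugEncoder
                from .cell_subcomponents import CellEncoder

                self.drug_enc = DrugEncoder(config.fp_width, F,
                                            config.gru_layers, rng)
                self.cell_enc = CellEncoder(n_sub, t_c, F,
                                            config.cnn_layers,
                                            config.cnn_kernel, rng)
                d_width = c_width = F
            self.omega = glorot(rng, (d_width, c_width))
            self.omega_bias = Tensor(np.array(config.interaction_bias))

            n_nodes = t_d + n_sub
            if "gated_graph" in ab:
                from .nn import GRUCell

                self.graph_embed = glorot(rng, (F, n_nodes))
                self.graph_msg = glorot(rng, (F, F))
                self.graph_cell = GRUCell(F, F, rng)
                h_width = 2 * F
            elif "no_graph" in ab:
                h_width = t_d * n_sub
            else:
                widths = [n_nodes] + [F] * config.gcn_layers
                self.thetas = [glorot(rng, (b, a))
                               for a, b in zip(widths[:-1], widths[1:])]
                h_width = 2 * F
        else:
            h_width = config.fp_width + dataset.masked_expr.shape[1]

        # side information (built from training responses only)
        if "no_side_info" not in ab:
            idx = np.arange(len(dataset)) if train_idx is None \
                else np.asarray(train_idx)
            train_inst = [dataset.instances[i] for i in idx]
            rm = build_response_matrix(train_inst, dataset.drug_index,
                                       dataset.cell_index)
            self.side_factors = factorize(rm, rank=config.side_rank,
                                          iters=config.side_iters,
                                          seed=config.seed)
            self.side_drug_seen = rm.mask.sum(axis=1) > 0
            self.side_cell_seen = rm.mask.sum(axis=0) > 0
            w = config.side_width
            self.fa_drug = [Linear(config.side_rank, w, rng),
                            Linear(w, w, rng)]
            self.fa_cell = [Linear(config.side_rank, w, rng),
                            Linear(w, w, rng)]
            self.bn_gamma = Tensor(np.ones(w), requires_grad=True)
            self.bn_beta = Tensor(np.zeros(w), requires_grad=True)
            side_w = 2 * w
        else:
            side_w = 0

        dec_in = h_width + side_w
        self.decoder = MLP([dec_in, *config.decoder_hidden, 1], rng,
                           dropout_p=config.dropout)

    # ------------------------------------------------------------------
    def parameters(self):
        params = []
        for enc in ("drug_enc", "cell_enc", "graph_cell", "decoder"):
            mod = getattr(self, enc, None)
            if mod is not None:
                params.extend(mod.parameters())
        for name in ("omega", "omega_bias", "graph_embed", "graph_msg",
                     "bn_gamma", "bn_beta"):
            t = getattr(self, name, None)
            if t is not None:
                params.append(t)
        for t in getattr(self, "thetas", []):
            params.append(t)
        for fa in (getattr(self, "fa_drug", []), getattr(self, "fa_cell", [])):
            for layer in fa:
                params.extend(layer.parameters())
        return params

    # ------------------------------------------------------------------
    def _side_rows(self, di, ci):
        if "no_side_info" in self.cfg.ablation:
            return None, None
        I_hat = self._fa(Tensor(self.side_factors.I.T), self.fa_drug)
        J_hat = self._fa(Tensor(self.side_factors.J.T), self.fa_cell)
        # cold-start entities (no training responses) fall back to zeros
        I_hat = I_hat * Tensor(self.side_drug_seen[:, None].astype(float))
        J_hat = J_hat * Tensor(self.side_cell_seen[:, None].astype(float))
        return I_hat.take_rows(di), J_hat.take_rows(ci)

    def _fa(self, x: Tensor, layers):
        for k, layer in enumerate(layers):
            x = layer(x)
            x = batch_norm(x, self.bn_gamma, self.bn_beta)
            if k < len(layers) - 1:
                x = x.leaky_relu()
        return x

    def _interaction(self, di, ci):
        """Batched interaction-map logits; returns (Omega, drug pad mask)."""
        mask = self.ds.drug_mask[di]                       # (B, t_d)
        if "no_sequence_encoders" in self.cfg.ablation:
            Dh = Tensor(self.ds.drug_feat[di])
            Ch = Tensor(self.ds.cell_feat[ci])
        else:
            Dh = self.drug_enc(Tensor(self.ds.drug_feat[di]))
            Ch = self.cell_enc(Tensor(self.ds.cell_feat[ci]))
        logits = (Dh @ self.omega) @ Ch.swapaxes(1, 2)     # (B, t_d, n)
        return (logits + self.omega_bias).sigmoid(), mask

    def _graph_summary(self, omega: Tensor, mask: np.ndarray):
        """Weighted bipartite propagation + global max/mean pooling."""
        B, t_d, n = omega.shape
        V = t_d + n
        masked = omega * Tensor(mask[:, :, None])
        zero_dd = Tensor(np.zeros((B, t_d, t_d)))
        zero_cc = Tensor(np.zeros((B, n, n)))
        top = concat([zero_dd, masked], axis=2)
        bottom = concat([masked.swapaxes(1, 2), zero_cc], axis=2)
        adj = concat([top, bottom], axis=1)                # (B, V, V)

        node_mask = np.concatenate(
            [mask, np.ones((B, n))], axis=1)               # (B, V)
        eye = np.eye(V)[None] * node_mask[:, :, None]      # self-loops on real nodes
        adj = adj + Tensor(eye)

        m_eff = mask.sum(axis=1)                           # (B,)
        deg = np.concatenate([np.where(mask > 0, n, 0.0),
                              np.tile(m_eff[:, None], (1, n))], axis=1)
        q = 1.0 + deg
        denom = q[:, :, None] * q[:, None, :]
        if self.cfg.gcn_norm == "sym_sqrt":
            denom = np.sqrt(denom)
        inv = Tensor(1.0 / denom)

        X = Tensor(np.broadcast_to(np.eye(V), (B, V, V)).copy()
                   * node_mask[:, :, None])

        if "gated_graph" in self.cfg.ablation:
            Z = X @ self.graph_embed.T
            for _ in range(self.cfg.gcn_layers):
                msg = ((adj * inv) @ Z) @ self.graph_msg.T
                Z = self.graph_cell.step(msg, Z)
        else:
            Z = X
            k_last = len(self.thetas) - 1
            for k, theta in enumerate(self.thetas):
                Z = ((adj * inv) @ Z) @ theta.T
                if not self.cfg.gcn_simplified or k == k_last:
                    Z = Z.leaky_relu()

        neg = Tensor((node_mask[:, :, None] - 1.0) * 1e9)
        zmax = (Z + neg).max(axis=1)
        counts = node_mask.sum(axis=1)[:, None]
        zmean = (Z * Tensor(node_mask[:, :, None])).sum(axis=1) * \
            Tensor(1.0 / counts)
        return concat([zmax, zmean], axis=1)

    def forward(self, di, ci, train: bool = False) -> Tensor:
        di = np.asarray(di, dtype=int)
        ci = np.asarray(ci, dtype=int)
        ab = self.cfg.ablation
        i_hat, j_hat = self._side_rows(di, ci)
        if "no_subcomponents" in ab:
            h = Tensor(np.concatenate(
                [self.ds.whole_fp[di], self.ds.masked_expr[ci]], axis=1))
        else:
            omega, mask = self._interaction(di, ci)
            if "no_graph" in ab:
                h = (omega * Tensor(mask[:, :, None])).reshape(len(di), -1)
            else:
                h = self._graph_summary(omega, mask)
        return decode(h, i_hat, j_hat, self.decoder, task=self.cfg.task,
                      rng=self.rng, train=train)

    def predict(self, di, ci) -> np.ndarray:
        return self.forward(di, ci, train=False).data

    def predict_pairs(self, pairs) -> np.ndarray:
        di = np.array([self.ds._dpos[d] for d, _ in pairs], dtype=int)
        ci = np.array([self.ds._cpos[c] for _, c in pairs], dtype=int)
        return self.predict(di, ci)

    def interaction_map(self, drug_id: str, cell_id: str) -> InteractionMap:
        """The trained interaction map for one instance (unpadded rows)."""
        if "no_subcomponents" in self.cfg.ablation:
            raise ValueError("no interaction map under the no_subcomponents "
                             "ablation")
        di = np.array([self.ds._dpos[drug_id]])
        ci = np.array([self.ds._cpos[cell_id]])
        omega, mask = self._interaction(di, ci)
        keep = mask[0] > 0
        frags = self.ds.sequences[drug_id].fragments
        scores = np.clip(omega.data[0][keep], 1e-12, 1.0 - 1e-12)
        return InteractionMap(scores,
                              row_labels=list(frags),
                              col_labels=list(self.ds.catalog.subset_labels))


def train(dataset: CDRDataset, config: ModelConfig, train_idx=None):
    """Seeded end-to-end training; returns (model, per-epoch loss history).

    Raises on a non-finite loss, naming the first offending epoch/batch.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    idx = np.arange(len(dataset)) if train_idx is None \
        else np.asarray(train_idx, dtype=int)
    model = SubCDRModel(dataset, config, train_idx=idx)
    opt = Adam(model.parameters(), lr=config.lr)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = []
    y = dataset.y if config.task == "regression" else dataset.labels.astype(float)
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(idx)
        losses, weights = [], []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            pred = model.forward(dataset.di[batch], dataset.ci[batch],
                                 train=True)
            if config.task == "regression":
                loss = huber_loss(pred, y[batch], delta=config.huber_delta)
            else:
                loss = _bce_loss(pred, y[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at "
                    f"instance {start}")
            opt.zero_grad()
            loss.backward()
            if config.weight_decay > 0:
                for p in opt.params:
                    if p.grad is not None:
                        p.grad += config.weight_decay * p.data
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(batch))
        history.append(float(np.average(losses, weights=weights)))
    return model, history


def train_interpretable(dataset: CDRDataset, config: ModelConfig,
                        train_idx=None, warmup_epochs: int = 80,
                        prune_epochs: int = 200, prune_decay: float = 2e-3,
                        other_decay: float = 5e-4):
    """Fit-then-prune training that sharpens interaction-map attribution.

    Phase one fits without any decay; phase two keeps fitting while L2
    decay (concentrated on the encoders and the bilinear matrix) pulls
    parameters that are not needed for prediction back toward zero.
    With the closed interaction initialization, scores of subcomponent
    pairs that do not carry signal relax to the low offset level while
    pairs the prediction depends on stay up the logistic — so the
    trained map's high scores mark the driving pairs.

    Returns (model, per-epoch loss history).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    idx = np.arange(len(dataset)) if train_idx is None \
        else np.asarray(train_idx, dtype=int)
    model = SubCDRModel(dataset, config, train_idx=idx)
    opt = Adam(model.parameters(), lr=config.lr)
    enc_params = {id(model.omega)}
    for name in ("drug_enc", "cell_enc"):
        mod = getattr(model, name, None)
        if mod is not None:
            enc_params.update(id(p) for p in mod.parameters())
    shuffle_rng = np.random.default_rng(config.seed + 1)
    history = []
    for epoch in range(warmup_epochs + prune_epochs):
        pruning = epoch >= warmup_epochs
        order = shuffle_rng.permutation(idx)
        losses, weights = [], []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            pred = model.forward(dataset.di[batch], dataset.ci[batch],
                                 train=True)
            loss = huber_loss(pred, dataset.y[batch],
                              delta=config.huber_delta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting at "
                    f"instance {start}")
            opt.zero_grad()
            loss.backward()
            if pruning:
                for p in opt.params:
                    if p.grad is not None:
                        wd = prune_decay if id(p) in enc_params else other_decay
                        p.grad += wd * p.data
            opt.step()
            losses.append(float(loss.data))
            weights.append(len(batch))
        history.append(float(np.average(losses, weights=weights)))
    return model, history


def evaluate(model: SubCDRModel, idx, task: str = None,
             group_keys=None) -> MetricsReport:
    """Standard regression/classification metrics on instance indices.

    ``group_keys`` (one key per instance, e.g. tumour type) adds
    per-group metric breakdowns.
    """
    from sklearn.metrics import (r2_score, roc_auc_score,
                                 average_precision_score)

    task = task or model.cfg.task
    idx = np.asarray(idx, dtype=int)
    pred = model.predict(model.ds.di[idx], model.ds.ci[idx])
    report = MetricsReport(n=len(idx))
    if task == "regression":
        truth = model.ds.y[idx]
        report.rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        report.pcc = float(np.corrcoef(pred, truth)[0, 1]) \
            if len(idx) > 1 and np.std(pred) > 0 and np.std(truth) > 0 else None
        report.r2 = float(r2_score(truth, pred)) if len(idx) > 1 else None
    else:
        labels = model.ds.labels[idx]
        if labels.min() == labels.max():
            report.undefined = True
        else:
            report.auc = float(roc_auc_score(labels, pred))
            report.aupr = float(average_precision_score(labels, pred))
    if group_keys is not None:
        keys = np.asarray(group_keys)
        for key in np.unique(keys):
            sub = idx[keys == key]
            if len(sub) >= 2:
                report.per_group[str(key)] = evaluate(model, sub, task=task)
    return report
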