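"""Interpretation utilities: heatmaps, top interactions, candidate ranking.

A trained interaction map is normalized with a softmax (whole-map by
default; per-row or per-column available) and exported as a labelled
delimited table; the highest-scoring (fragment, subset) pairs expose
which subcomponents drive a prediction. For discovery, unmeasured
drug/cell pairs are scored by the trained model, filtered to predicted
ln-IC50 below a sensitivity threshold, and the lowest-k retained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .interaction import InteractionMap

__all__ = [
    "HeatmapExport", "CandidateRanking", "normalize_map", "top_interactions",
    "rank_candidates",
]


@dataclass
class HeatmapExport:
    """Softmax-normalized interaction map with labels."""

    scores: np.ndarray
    row_labels: list
    col_labels: list
    axis: object = None                # None = whole-map softmax
    instance_id: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.row_labels,
                            columns=self.col_labels)

    def to_tsv(self, path=None) -> str:
        text = self.to_frame().to_csv(sep="\t", float_format="%.17g")
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_tsv(cls, source) -> "HeatmapExport":
        if isinstance(source, str) and "\t" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.index),
                   list(df.columns))

    def to_png(self, path):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(1 + 0.6 * len(self.col_labels),
                                        1 + 0.5 * len(self.row_labels)))
        im = ax.imshow(self.scores, cmap="viridis")
        ax.set_xticks(range(len(self.col_labels)), self.col_labels,
                      rotation=45, ha="right")
        ax.set_yticks(range(len(self.row_labels)), self.row_labels)
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


@dataclass
class CandidateRanking:
    """Unmeasured pairs predicted sensitive, lowest predictions first."""

    entries: list                      # [(drug_id, cell_id, prediction)]
    k: int
    threshold: float
    status: str = "ok"

    def __post_init__(self):
        preds = [e[2] for e in self.entries]
        if preds != sorted(preds):
            raise ValueError("ranking must be sorted ascending by prediction")
        if any(p >= self.threshold for p in preds):
            raise ValueError("retained entries must be below the threshold")


def _as_map(imap) -> InteractionMap:
    """Coerce a plain 2-D array into a labelled map container."""
    if isinstance(imap, InteractionMap):
        return imap
    arr = np.asarray(imap, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("map must be a non-empty 2-D matrix")
    out = InteractionMap.__new__(InteractionMap)
    out.scores = arr
    out.row_labels = [f"frag_{i}" for i in range(arr.shape[0])]
    out.col_labels = [f"subset_{j}" for j in range(arr.shape[1])]
    return out


def normalize_map(imap, axis=None) -> HeatmapExport:
    """Softmax-normalize an interaction map for heatmap display.

    ``imap`` may be an :class:`InteractionMap` or a plain 2-D array.
    ``axis=None`` normalizes over the whole map (entries sum to 1);
    ``axis=0``/``axis=1`` normalize per column / per row.
    """
    imap = _as_map(imap)
    s = imap.scores
    if axis is None:
        norm = softmax(s.ravel()).reshape(s.shape)
    elif axis in (0, 1):
        norm = softmax(s, axis=axis)
    else:
        raise ValueError("axis must be None, 0 or 1")
    return HeatmapExport(norm, list(imap.row_labels), list(imap.col_labels),
                         axis=axis)


def top_interactions(imap, k: int = 5):
    """Highest-scoring (fragment, subset, score) triples, descending.

    Ties break deterministically by (row index, column index). If k
    exceeds the map size all cells are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    imap = _as_map(imap)
    m, n = imap.shape
    cells = [(i, j, float(imap.scores[i, j]))
             for i in range(m) for j in range(n)]
    cells.sort(key=lambda t: (-t[2], t[0], t[1]))
    return [(imap.row_labels[i], imap.col_labels[j], s)
            for i, j, s in cells[:min(k, m * n)]]


def rank_candidates(model, pairs, k: int = 10,
                    threshold: float = -2.0) -> CandidateRanking:
    """Rank unmeasured (drug, cell) pairs by predicted response.

    Predictions are computed for every pair; only those strictly below
    ``threshold`` (predicted sensitive) are kept and the k lowest are
    returned in ascending order.
    """
    pairs = list(pairs)
    preds = model.predict_pairs(pairs)
    scored = sorted(
        ((d, c, float(p)) for (d, c), p in zip(pairs, preds) if p < threshold),
        key=lambda t: (t[2], t[0], t[1]))
    status = "ok" if scored else "no pair predicted below threshold"
    return CandidateRanking(scored[:k], k=k, threshold=threshold,
                            status=status)
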