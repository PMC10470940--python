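"""Cell-line decomposition into cancer-gene subsets and their encoding.

Cancer Gene Census (CGC) genes are partitioned into disjoint role
subsets (oncogene, TSG, fusion, unknown, and their overlaps). A
tumour-type mask zeroes genes not annotated as relevant to the cell
line's tumour type, and the resulting subset expression vectors are
zero-padded to a common width and encoded by a small 1-D CNN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .nn import Conv1d, Linear, Module

__all__ = [
    "GeneCatalog", "CellSubsetProfile", "CellEncoder", "partition_genes",
    "apply_tumour_mask", "build_profile", "encode_cell",
]


@dataclass
class GeneCatalog:
    """Ordered gene list with disjoint subset labels and tumour-type sets."""

    genes: list
    category_of: dict                  # gene -> subset label
    tumour_types_of: dict              # gene -> set of tumour types
    subset_labels: list = field(default=None)

    def __post_init__(self):
        missing = [g for g in self.genes if g not in self.category_of]
        if missing:
            raise ValueError(f"genes without a category: {missing[:5]}")
        if self.subset_labels is None:
            seen = []
            for g in self.genes:
                lab = self.category_of[g]
                if lab not in seen:
                    seen.append(lab)
            self.subset_labels = seen

    @classmethod
    def from_annotation(cls, annot: pd.DataFrame) -> "GeneCatalog":
        """Build from a ``gene,category,tumour_types`` annotation table.

        Genes annotated with several roles (semicolon-separated
        category) form their own overlap subset, keeping subsets
        disjoint.
        """
        genes = annot["gene"].tolist()
        category = {}
        ttypes = {}
        for _, row in annot.iterrows():
            parts = sorted(str(row["category"]).split(";"))
            category[row["gene"]] = "+".join(parts) if len(parts) > 1 else parts[0]
            raw = str(row["tumour_types"]) if pd.notna(row["tumour_types"]) else ""
            ttypes[row["gene"]] = {t for t in raw.split(";") if t}
        return cls(genes, category, ttypes)

    @property
    def n_subsets(self) -> int:
        return len(self.subset_labels)

    def subset_genes(self, label: str) -> list:
        return [g for g in self.genes if self.category_of[g] == label]

    @property
    def t_c(self) -> int:
        """Largest subset size: the common padded subset width."""
        return max(len(self.subset_genes(lab)) for lab in self.subset_labels)

    def subset_assignment(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes,
                             "subset_label": [self.category_of[g]
                                              for g in self.genes]})


@dataclass
class CellSubsetProfile:
    """Masked, zero-padded subset expression vectors of one cell line."""

    cell_id: str
    subsets: np.ndarray                # (n_subsets, t_c)
    mask_applied: np.ndarray           # binary over catalog genes


def partition_genes(catalog: GeneCatalog, expression_row: pd.Series):
    """Split one expression row into the catalog's n subset vectors.

    Subset-internal gene order follows catalog order; each gene lands in
    exactly one subset.
    """
    missing = [g for g in catalog.genes if g not in expression_row.index]
    if missing:
        raise KeyError(f"expression row is missing gene(s) {missing[:5]}")
    return [expression_row[catalog.subset_genes(lab)].to_numpy(dtype=float)
            for lab in catalog.subset_labels]


def tumour_mask(catalog: GeneCatalog, tumour_type: str,
                strict: bool = True) -> np.ndarray:
    """Binary gene vector: 1 where the gene is annotated for the tumour type."""
    known = set().union(*catalog.tumour_types_of.values()) \
        if catalog.tumour_types_of else set()
    if tumour_type not in known:
        if strict:
            raise KeyError(f"unknown tumour type {tumour_type!r}")
        return np.ones(len(catalog.genes))
    return np.array([1.0 if tumour_type in catalog.tumour_types_of[g] else 0.0
                     for g in catalog.genes])


def apply_tumour_mask(expression_row: pd.Series, tumour_type: str,
                      catalog: GeneCatalog, strict: bool = True) -> pd.Series:
    """Zero the expression of genes not relevant to the cell's tumour type."""
    mask = tumour_mask(catalog, tumour_type, strict=strict)
    row = expression_row[catalog.genes].astype(float)
    return pd.Series(row.to_numpy() * mask, index=catalog.genes,
                     name=expression_row.name)


def build_profile(cell_id: str, expression_row: pd.Series, tumour_type: str,
                  catalog: GeneCatalog, strict: bool = True) -> CellSubsetProfile:
    """Mask, partition and zero-pad one cell line into its subset profile."""
    mask = tumour_mask(catalog, tumour_type, strict=strict)
    masked = apply_tumour_mask(expression_row, tumour_type, catalog,
                               strict=strict)
    vectors = partition_genes(catalog, masked)
    t_c = catalog.t_c
    subsets = np.zeros((catalog.n_subsets, t_c))
    for i, v in enumerate(vectors):
        subsets[i, :len(v)] = v
    return CellSubsetProfile(cell_id, subsets, mask)


class CellEncoder(Module):
    """Stacked same-padded 1-D convolutions plus a linear width map.

    Input (batch, n_subsets, t_c); output (batch, n_subsets, F) so the
    cell-side latent width matches the drug encoder's hidden width F.
    Convolutions are depthwise (one channel per gene subset) so row i of
    the output stays attributable to subset i.
    """

    def __init__(self, n_subsets: int, t_c: int, out_width: int = 64,
                 num_layers: int = 2, kernel: int = 3, rng=None,
                 depthwise: bool = True):
        rng = np.random.default_rng(0) if rng is None else rng
        self.convs = [Conv1d(n_subsets, n_subsets, kernel, rng,
                             depthwise=depthwise)
                      for _ in range(num_layers)]
        self.proj = Linear(t_c, out_width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for i, conv in enumerate(self.convs):
            x = conv(x)
            if i < len(self.convs) - 1:
                x = x.leaky_relu()
        return self.proj(x)


def encode_cell(profile: CellSubsetProfile, encoder: CellEncoder) -> np.ndarray:
    """Encode one profile; returns the (n_subsets, F) latent matrix."""
    t_c = encoder.proj.W.shape[1]
    if profile.subsets.shape[1] != t_c:
        raise ValueError(
            f"profile width {profile.subsets.shape[1]} != encoder t_c {t_c}")
    return encoder(Tensor(profile.subsets[None, :, :])).data[0]
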