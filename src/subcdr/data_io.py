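"""Input tables, response matrix assembly, binarization and CV splits.

The five delimited input tables are:

* response table: ``drug_id,cell_id,ln_ic50`` — one row per measured
  drug/cell-line pair, natural-log IC50;
* drug table: ``drug_id,smiles``;
* expression table: first column the cell-line id, remaining columns one
  per gene symbol (log2-TPM, z-scored);
* gene annotation: ``gene,category,tumour_types`` with tumour types
  semicolon-separated;
* cell annotation: ``cell_id,tumour_type``.

Loading collapses duplicated (drug, cell) pairs keeping the *highest*
ln-IC50, merges drugs that share one compound (identical canonical
SMILES), and drops responses for cell lines without expression rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "CDRInstance", "ResponseMatrix", "FoldAssignment", "LoadReport",
    "SchemaError", "RowParseError", "load_tables", "build_response_matrix",
    "binarize", "make_folds", "split_independent", "BINARIZE_THRESHOLD",
]

#: ln(IC50) below which an instance counts as sensitive (positive);
#: exp(-2.0) ~ 0.135 uM.
BINARIZE_THRESHOLD = -2.0


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class RowParseError(ValueError):
    """A numeric field failed to parse; carries the 1-based line number."""


@dataclass(frozen=True)
class CDRInstance:
    """One (drug, cell line, ln-IC50) record, optionally binarized."""

    drug_id: str
    cell_id: str
    response: float
    label: Optional[int] = None

    def __post_init__(self):
        if not np.isfinite(self.response):
            raise ValueError(
                f"non-finite response for ({self.drug_id}, {self.cell_id})")


@dataclass
class ResponseMatrix:
    """Drugs x cell-lines matrix of known responses with observation mask.

    Unmeasured entries store 0.0 under ``values`` with ``mask`` 0; all
    consumers must consult the mask, never the sentinel value.
    """

    values: np.ndarray
    mask: np.ndarray
    drug_index: list
    cell_index: list

    def __post_init__(self):
        if len(set(self.drug_index)) != len(self.drug_index):
            raise ValueError("duplicate ids in drug_index")
        if len(set(self.cell_index)) != len(self.cell_index):
            raise ValueError("duplicate ids in cell_index")

    @property
    def n_unmeasured(self) -> int:
        return int(self.mask.size - self.mask.sum())


@dataclass
class FoldAssignment:
    scenario: str                      # warm | cold_cell | cold_drug
    folds: list                       # [(train_idx, test_idx), ...]
    seed: int


@dataclass
class LoadReport:
    n_response_rows: int = 0
    n_instances: int = 0
    n_duplicates_collapsed: int = 0
    n_dropped_no_expression: int = 0
    n_dropped_unknown_drug: int = 0
    n_drugs_merged: int = 0
    notes: list = field(default_factory=list)


def _require_columns(df: pd.DataFrame, cols, table: str):
    for c in cols:
        if c not in df.columns:
            raise SchemaError(f"{table} table is missing required column '{c}'")


def _read_csv(path, table):
    try:
        return pd.read_csv(path, dtype=str, skipinitialspace=True)
    except FileNotFoundError:
        raise FileNotFoundError(f"{table} table not found: {path}")


def load_tables(response_path, smiles_path, expression_path,
                gene_annot_path, cell_annot_path):
    """Load and validate the five input tables.

    Returns ``(instances, drug_table, expression, gene_annot, cell_annot,
    report)`` where ``instances`` is a list of :class:`CDRInstance` after
    de-duplication, drug merging and dropping of cells without
    expression rows.
    """
    from rdkit import Chem

    resp = _read_csv(response_path, "response")
    _require_columns(resp, ["drug_id", "cell_id", "ln_ic50"], "response")
    drugs = _read_csv(smiles_path, "drug")
    _require_columns(drugs, ["drug_id", "smiles"], "drug")
    expr = pd.read_csv(expression_path, index_col=0)
    gene_annot = _read_csv(gene_annot_path, "gene annotation")
    _require_columns(gene_annot, ["gene", "category", "tumour_types"],
                     "gene annotation")
    cell_annot = _read_csv(cell_annot_path, "cell annotation")
    _require_columns(cell_annot, ["cell_id", "tumour_type"], "cell annotation")

    report = LoadReport(n_response_rows=len(resp))

    # parse ln_ic50 with line-numbered errors (header = line 1)
    values = np.empty(len(resp))
    for pos, raw in enumerate(resp["ln_ic50"].tolist()):
        try:
            values[pos] = float(raw)
        except (TypeError, ValueError):
            raise RowParseError(
                f"response table line {pos + 2}: cannot parse ln_ic50 {raw!r}")
    resp = resp.assign(ln_ic50=values)

    # merge drugs sharing one compound (identical canonical SMILES)
    canon = {}
    drug_alias = {}
    kept_rows = []
    for _, row in drugs.iterrows():
        mol = Chem.MolFromSmiles(row["smiles"])
        key = Chem.MolToSmiles(mol) if mol is not None else row["smiles"]
        if key in canon:
            drug_alias[row["drug_id"]] = canon[key]
            report.n_drugs_merged += 1
        else:
            canon[key] = row["drug_id"]
            drug_alias[row["drug_id"]] = row["drug_id"]
            kept_rows.append(row)
    drug_table = pd.DataFrame(kept_rows).reset_index(drop=True)

    known_drugs = set(drug_table["drug_id"])
    known_cells = set(expr.index.astype(str))

    best: dict = {}
    for _, row in resp.iterrows():
        did = drug_alias.get(row["drug_id"], row["drug_id"])
        if did not in known_drugs:
            report.n_dropped_unknown_drug += 1
            continue
        cid = str(row["cell_id"])
        if cid not in known_cells:
            report.n_dropped_no_expression += 1
            continue
        key = (did, cid)
        if key in best:
            report.n_duplicates_collapsed += 1
            best[key] = max(best[key], float(row["ln_ic50"]))
        else:
            best[key] = float(row["ln_ic50"])

    instances = [CDRInstance(d, c, v) for (d, c), v in best.items()]
    report.n_instances = len(instances)
    return instances, drug_table, expr, gene_annot, cell_annot, report


def build_response_matrix(instances, drug_index, cell_index) -> ResponseMatrix:
    """Assemble the (drugs x cells) training response matrix with mask."""
    drug_pos = {d: i for i, d in enumerate(drug_index)}
    cell_pos = {c: j for j, c in enumerate(cell_index)}
    values = np.zeros((len(drug_index), len(cell_index)))
    mask = np.zeros_like(values)
    for inst in instances:
        if inst.drug_id not in drug_pos:
            raise KeyError(f"drug id {inst.drug_id!r} not in drug_index")
        if inst.cell_id not in cell_pos:
            raise KeyError(f"cell id {inst.cell_id!r} not in cell_index")
        i, j = drug_pos[inst.drug_id], cell_pos[inst.cell_id]
        values[i, j] = inst.response
        mask[i, j] = 1.0
    return ResponseMatrix(values, mask, list(drug_index), list(cell_index))


def binarize(instances, threshold: float = BINARIZE_THRESHOLD):
    """Attach sensitivity labels: 1 iff response strictly below threshold."""
    return [replace(inst, label=int(inst.response < threshold))
            for inst in instances]


def make_folds(instances, scenario: str, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Build k-fold cross-validation splits for one evaluation scenario.

    ``warm`` shuffles instances into k near-equal parts; ``cold_cell`` /
    ``cold_drug`` split the entity set so no test entity appears in
    training. Fold contents are index lists into ``instances``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(instances)
    if scenario == "warm":
        order = rng.permutation(n)
        parts = np.array_split(order, k)
    elif scenario in ("cold_cell", "cold_drug"):
        attr = "cell_id" if scenario == "cold_cell" else "drug_id"
        entities = sorted({getattr(inst, attr) for inst in instances})
        if len(entities) < k:
            raise ValueError(
                f"{scenario}: only {len(entities)} entities for k={k} folds")
        perm = [entities[i] for i in rng.permutation(len(entities))]
        groups = np.array_split(np.arange(len(perm)), k)
        parts = []
        for g in groups:
            held = {perm[i] for i in g}
            parts.append(np.array([i for i, inst in enumerate(instances)
                                   if getattr(inst, attr) in held], dtype=int))
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    all_idx = set(range(n))
    folds = []
    for part in parts:
        test = sorted(int(i) for i in part)
        train = sorted(all_idx - set(test))
        folds.append((train, test))
    return FoldAssignment(scenario=scenario, folds=folds, seed=seed)


def split_independent(instances, test_fraction: float = 0.1, seed: int = 0):
    """Seeded random split into cross-validation and independent test sets."""
    rng = np.random.default_rng(seed)
    n = len(instances)
    order = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_idx = set(order[:n_test].tolist())
    cv = [inst for i, inst in enumerate(instances) if i not in test_idx]
    test = [inst for i, inst in enumerate(instances) if i in test_idx]
    return cv, test
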