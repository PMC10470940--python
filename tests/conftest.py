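import numpy as np
import pandas as pd
import pytest

from subcdr.cell_subcomponents import GeneCatalog
from subcdr.data_io import CDRInstance


@pytest.fixture
def toy_tables(tmp_path):
    """3 drugs x 4 cells with one duplicated pair and one orphan cell row.

    The duplicated (D1, C1) pair carries responses {1.0, 2.5}; cell C9
    has responses but no expression row. A clean load yields 11
    instances.
    """
    drugs = pd.DataFrame({
        "drug_id": ["D1", "D2", "D3"],
        "smiles": ["CC(=O)Oc1ccccc1C(=O)O", "c1ccccc1", "CCOCC"],
    })
    genes = [f"G{i}" for i in range(6)]
    cells = ["C1", "C2", "C3", "C4"]
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.standard_normal((4, 6)), index=cells,
                        columns=genes)
    gene_annot = pd.DataFrame({
        "gene": genes,
        "category": ["oncogene", "oncogene", "oncogene", "TSG", "TSG",
                     "fusion"],
        "tumour_types": ["lung;breast", "lung", "breast", "lung;breast",
                         "lung", "lung;breast"],
    })
    cell_annot = pd.DataFrame({
        "cell_id": cells + ["C9"],
        "tumour_type": ["lung", "breast", "lung", "breast", "lung"],
    })
    rows = []
    for d in ["D1", "D2", "D3"]:
        for c in cells:
            rows.append((d, c, round(rng.normal(), 3)))
    resp = pd.DataFrame(rows, columns=["drug_id", "cell_id", "ln_ic50"])
    # duplicate pair with responses 1.0 / 2.5 and one orphan-cell row
    resp.loc[resp.index[(resp.drug_id == "D1") & (resp.cell_id == "C1")],
             "ln_ic50"] = 1.0
    resp = pd.concat([resp, pd.DataFrame(
        [("D1", "C1", 2.5), ("D2", "C9", 0.7)],
        columns=resp.columns)], ignore_index=True)
    # drop one pair so the grid is not full: 3*4 = 12 - 1 = 11 kept pairs
    resp = resp[~((resp.drug_id == "D3") & (resp.cell_id == "C4"))]

    paths = {}
    for name, df in [("response", resp), ("drugs", drugs),
                     ("gene_annot", gene_annot), ("cell_annot", cell_annot)]:
        p = tmp_path / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    p = tmp_path / "expression.csv"
    expr.to_csv(p)
    paths["expression"] = p
    paths["expr_df"] = expr
    paths["gene_annot_df"] = gene_annot
    return paths


@pytest.fixture
def toy_catalog():
    genes = ["G0", "G1", "G2", "G3", "G4", "G5"]
    annot = pd.DataFrame({
        "gene": genes,
        "category": ["onc", "onc", "onc", "tsg", "tsg", "fus"],
        "tumour_types": ["lung;breast", "lung", "breast", "lung;breast",
                         "lung", "lung;breast"],
    })
    return GeneCatalog.from_annotation(annot)


@pytest.fixture
def small_world():
    from subcdr.fixtures import generate_world

    return generate_world(n_drugs=6, n_cells=8, n_genes=12, n_subsets=3,
                          seed=11)


@pytest.fixture
def instances_100():
    rng = np.random.default_rng(5)
    return [CDRInstance(f"D{i % 10}", f"C{i % 20}", float(rng.normal()))
            for i in range(100)]
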