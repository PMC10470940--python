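"""Drug decomposition into ordered BRICS fragments and their encoding.

A drug SMILES is cleaved at retrosynthetically meaningful bonds
(BRICS). Fragments carry dummy atoms ``*`` at the cut sites and are
ordered by the position of their first real atom in the input SMILES
left-to-right scan, so the sequence follows the molecule as written.
Each fragment is embedded as a binary circular (Morgan/ECFP)
fingerprint, and fragment sequences are encoded with a stacked gated
recurrent unit.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import GRU

__all__ = [
    "SubcomponentSequence", "DrugEncoder", "brics_decompose",
    "strip_dummy_labels", "embed_fragments", "build_sequence",
    "max_fragment_count",
]

_DUMMY_LABEL = re.compile(r"\[\d+\*\]")


class SmilesParseError(ValueError):
    """SMILES string could not be parsed into a molecule."""


@dataclass
class SubcomponentSequence:
    """Ordered drug fragments with fingerprint features and padding mask.

    ``features`` has shape (t_d, width); rows beyond the real fragment
    count are zero. ``pad_mask`` holds exactly ``len(fragments)`` leading
    ones.
    """

    drug_id: str
    fragments: list
    features: np.ndarray
    pad_mask: np.ndarray

    def __post_init__(self):
        m = len(self.fragments)
        if self.pad_mask.sum() != m or not np.all(self.pad_mask[:m] == 1):
            raise ValueError("pad_mask must have exactly m leading ones")


def strip_dummy_labels(smiles: str) -> str:
    """Replace isotope-labelled dummy atoms (e.g. ``[1*]``) by bare ``*``."""
    return _DUMMY_LABEL.sub("*", smiles)


def brics_decompose(smiles: str) -> list:
    """Cleave a molecule at BRICS bonds into an ordered fragment list.

    Fragments retain their labelled dummy atoms; ordering follows the
    first real atom of each fragment in the input SMILES scan. A
    molecule with no breakable BRICS bond is returned as one fragment.
    """
    from rdkit import Chem
    from rdkit.Chem import BRICS

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES {smiles!r}")
    n_real = mol.GetNumAtoms()
    broken = BRICS.BreakBRICSBonds(mol)
    frag_atom_ids = Chem.GetMolFrags(broken)
    frag_mols = Chem.GetMolFrags(broken, asMols=True)
    # BreakBRICSBonds keeps original atom indices for real atoms and
    # appends dummies, so the smallest original index orders fragments.
    order = np.argsort([min(a for a in ids if a < n_real)
                        for ids in frag_atom_ids])
    return [Chem.MolToSmiles(frag_mols[i]) for i in order]


def embed_fragments(fragments, radius: int = 2, width: int = 512,
                    include_dummies: bool = True) -> np.ndarray:
    """Morgan/ECFP bit-vector per fragment, shape (m, width), entries {0,1}."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=width)
    out = np.zeros((len(fragments), width))
    for i, frag in enumerate(fragments):
        mol = Chem.MolFromSmiles(frag)
        if mol is None:
            raise SmilesParseError(f"cannot sanitize fragment {frag!r}")
        if not include_dummies:
            mol = Chem.DeleteSubstructs(mol, Chem.MolFromSmarts("[#0]"))
        fp = gen.GetFingerprint(mol)
        out[i, list(fp.GetOnBits())] = 1.0
    return out


def max_fragment_count(smiles_by_drug: dict) -> int:
    """Corpus-wide maximum fragment count t_d."""
    return max(len(brics_decompose(s)) for s in smiles_by_drug.values())


def build_sequence(drug_id: str, smiles: str, t_d: int, radius: int = 2,
                   width: int = 512) -> SubcomponentSequence:
    """Decompose, fingerprint and zero-pad one drug to length ``t_d``."""
    fragments = brics_decompose(smiles)
    if len(fragments) > t_d:
        warnings.warn(
            f"drug {drug_id}: {len(fragments)} fragments exceed t_d={t_d}; "
            "truncating tail fragments")
        fragments = fragments[:t_d]
    feats = embed_fragments(fragments, radius=radius, width=width)
    features = np.zeros((t_d, width))
    features[:len(fragments)] = feats
    pad_mask = np.zeros(t_d)
    pad_mask[:len(fragments)] = 1.0
    return SubcomponentSequence(drug_id, fragments, features, pad_mask)


class DrugEncoder(GRU):
    """Stacked GRU mapping fingerprint sequences to contextual features.

    Two unidirectional layers by default; the initial hidden state is
    the zero vector. Padded positions produce states that downstream
    consumers must ignore via the padding mask.
    """

    def __init__(self, in_width: int = 512, hidden: int = 64,
                 num_layers: int = 2, rng=None):
        rng = np.random.default_rng(0) if rng is None else rng
        super().__init__(in_width, hidden, num_layers, rng)


def encode_drug(sequence: SubcomponentSequence, encoder: DrugEncoder):
    """Encode one padded sequence; returns (t_d, F) array and the pad mask."""
    if sequence.features.shape[1] != encoder.cells[0].Wr.shape[1]:
        raise ValueError(
            f"feature width {sequence.features.shape[1]} does not match "
            f"encoder input width {encoder.cells[0].Wr.shape[1]}")
    out = encoder(Tensor(sequence.features[None, :, :]))
    return out.data[0], sequence.pad_mask
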