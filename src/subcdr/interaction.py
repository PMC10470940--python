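"""Subcomponent interaction maps and the bipartite graph convolution.

Every (drug fragment, gene subset) pair is scored with a trainable
bilinear form through a logistic squashing, giving the interaction map
Omega in (0,1)^(m x n) — the model's interpretability surface. The map
is lifted to a weighted complete bipartite graph whose nodes are the
subcomponents and whose edge weights are the scores; graph convolutions
propagate over it and a global max/mean pooling summarizes the node
embeddings into a fixed-width vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "InteractionMap", "GCNParams", "score_interactions", "build_graph",
    "gcn_forward", "pool", "graph_matrices",
]


#: keep saturated logistic outputs strictly inside (0,1) in float64
_EPS = 1e-12


def _sigmoid(x):
    from scipy.special import expit

    return np.clip(expit(x), _EPS, 1.0 - _EPS)


@dataclass
class InteractionMap:
    """Sigmoid-scored subcomponent interactions for one instance.

    ``scores`` has shape (m_effective, n): rows are real (unpadded) drug
    fragments, columns are cell gene subsets; every entry lies strictly
    inside (0, 1).
    """

    scores: np.ndarray
    row_labels: list = field(default=None)
    col_labels: list = field(default=None)

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 2 or s.size == 0:
            raise ValueError("interaction map must be a non-empty 2-D matrix")
        if np.any(s <= 0) or np.any(s >= 1):
            raise ValueError("interaction scores must lie strictly in (0,1)")
        self.scores = s
        if self.row_labels is None:
            self.row_labels = [f"frag_{i}" for i in range(s.shape[0])]
        if self.col_labels is None:
            self.col_labels = [f"subset_{j}" for j in range(s.shape[1])]

    @property
    def shape(self):
        return self.scores.shape


def score_interactions(d_hat: np.ndarray, c_hat: np.ndarray, omega: np.ndarray,
                       pad_mask=None, row_labels=None,
                       col_labels=None) -> InteractionMap:
    """Bilinear interaction scores ``sigmoid(d_i . omega . c_j^T)``.

    ``d_hat`` is (t_d, F), ``c_hat`` is (n, F), ``omega`` is (F, F);
    rows of padded fragments are removed according to ``pad_mask``.
    """
    d_hat, c_hat, omega = map(np.asarray, (d_hat, c_hat, omega))
    if d_hat.shape[1] != omega.shape[0] or c_hat.shape[1] != omega.shape[1]:
        raise ValueError(
            f"width mismatch: d {d_hat.shape}, omega {omega.shape}, "
            f"c {c_hat.shape}")
    logits = d_hat @ omega @ c_hat.T
    if pad_mask is not None:
        keep = np.asarray(pad_mask, dtype=bool)
        logits = logits[keep]
        if row_labels is not None:
            row_labels = [lab for lab, k in zip(row_labels, keep) if k]
    return InteractionMap(_sigmoid(logits), row_labels, col_labels)


def build_graph(imap: InteractionMap) -> nx.Graph:
    """Weighted complete bipartite graph over the map's subcomponents.

    Drug-fragment nodes are ``("d", i)`` (bipartite set 0), cell-subset
    nodes ``("c", j)`` (set 1); edge weights are the interaction
    scores. Node attribute ``onehot`` is the index of the node's 1 in
    the identity attribute matrix.
    """
    m, n = imap.shape
    g = nx.Graph()
    for i in range(m):
        g.add_node(("d", i), bipartite=0, onehot=i, label=imap.row_labels[i])
    for j in range(n):
        g.add_node(("c", j), bipartite=1, onehot=m + j,
                   label=imap.col_labels[j])
    for i in range(m):
        for j in range(n):
            g.add_edge(("d", i), ("c", j), weight=float(imap.scores[i, j]))
    return g


def graph_matrices(g: nx.Graph, attr_width: int = None):
    """Node ordering, weighted adjacency (with unit self-loops) and one-hot X."""
    nodes = sorted(g.nodes, key=lambda v: g.nodes[v]["onehot"])
    nv = len(nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
    adj = adj + np.eye(nv)                      # a_vv = 1
    width = nv if attr_width is None else attr_width
    if width < nv:
        raise ValueError("attribute width smaller than node count")
    x = np.zeros((nv, width))
    x[np.arange(nv), np.arange(nv)] = 1.0
    return nodes, adj, x


@dataclass
class GCNParams:
    """Per-layer trainable matrices and propagation options.

    ``norm`` selects the neighbour normalization: ``"product"`` divides
    each edge term by q_v * q_u (q = 1 + degree), ``"sym_sqrt"`` by
    sqrt(q_v * q_u). ``simplified`` drops the intermediate
    nonlinearities (simplifying-GCN variant), keeping layers linear.
    """

    thetas: list
    norm: str = "product"
    simplified: bool = False
    leaky_slope: float = 0.01
    activation: str = "leaky_relu"    # or "linear"

    def __post_init__(self):
        if len(self.thetas) < 1:
            raise ValueError("GCN needs at least one layer")
        if self.norm not in ("product", "sym_sqrt"):
            raise ValueError(f"unknown norm {self.norm!r}")


def normalized_propagation_matrix(adj: np.ndarray, norm: str = "product"):
    """Eq-style propagation operator N with N[v,u] = a_vu / f(q_v, q_u).

    ``adj`` already includes unit self-loops; q_v counts neighbours
    excluding the self-loop, plus one.
    """
    deg = (adj > 0).sum(axis=1) - 1            # neighbours, self-loop removed
    q = 1.0 + deg
    denom = np.outer(q, q)
    if norm == "sym_sqrt":
        denom = np.sqrt(denom)
    return adj / denom


def _activate(z, params: GCNParams):
    if params.activation == "linear":
        return z
    return np.where(z > 0, z, params.leaky_slope * z)


def gcn_forward(g: nx.Graph, params: GCNParams,
                attr_width: int = None) -> np.ndarray:
    """Run K rounds of weighted-neighbour propagation over the graph.

    Node embeddings start at the one-hot attributes; each layer applies
    the normalized weighted sum over the closed neighbourhood followed
    by the layer activation (skipped between layers in simplified mode).
    """
    _, adj, x = graph_matrices(g, attr_width)
    nmat = normalized_propagation_matrix(adj, params.norm)
    z = x
    k_last = len(params.thetas) - 1
    for k, theta in enumerate(params.thetas):
        z = nmat @ z @ np.asarray(theta).T
        if not params.simplified or k == k_last:
            z = _activate(z, params)
    return z


def pool(z: np.ndarray) -> np.ndarray:
    """Global summary [column-max || column-mean] over node embeddings."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("cannot pool an empty embedding matrix")
    return np.concatenate([z.max(axis=0), z.mean(axis=0)])
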