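"""Low-rank side information from the masked training response matrix.

The known training responses form a drugs x cells matrix R with an
observation mask M. Minimizing ``1/2 * ||M o (R - I^T J)||_F^2`` over
the low-rank factors I (rank x drugs) and J (rank x cells) yields
collaborative-filtering-style latent factors; a small fully-connected
map turns them into the side-information vectors concatenated into the
decoder. Only training-partition responses ever enter R, and the
factors are rebuilt per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import ResponseMatrix

__all__ = [
    "SideFactors", "SideInfo", "factorize", "masked_objective", "transform",
    "lookup",
]


@dataclass
class SideFactors:
    I: np.ndarray                      # (rank, |drugs|)
    J: np.ndarray                      # (rank, |cells|)
    rank: int
    final_objective: float
    drug_index: list
    cell_index: list
    history: list = None


@dataclass
class SideInfo:
    I_hat: np.ndarray                  # (|drugs|, width)
    J_hat: np.ndarray                  # (|cells|, width)
    drug_index: list
    cell_index: list


def masked_objective(R: np.ndarray, M: np.ndarray, I: np.ndarray,
                     J: np.ndarray) -> float:
    """``1/2 * ||M o (R - I^T J)||_F^2``."""
    E = M * (R - I.T @ J)
    return 0.5 * float(np.sum(E * E))


def factorize(rm: ResponseMatrix, rank: int = 16, iters: int = 500,
              lr: float = 0.01, seed: int = 0,
              method: str = "gd") -> SideFactors:
    """Fit the masked low-rank factorization of the response matrix.

    ``method="gd"`` runs gradient descent with backtracking step
    acceptance, so the recorded objective history is non-increasing;
    ``method="als"`` alternates ridge-regularized least-squares row
    solves; ``method="svd_impute"`` takes a truncated SVD of the
    zero-imputed matrix (no masked objective minimization).
    """
    R, M = rm.values, rm.mask
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if M.sum() == 0:
        raise ValueError("no training responses: the observation mask is empty")
    rng = np.random.default_rng(seed)
    nd, nc = R.shape
    scale = np.sqrt(np.abs(R[M > 0]).mean() / max(rank, 1) + 1e-12)
    I = rng.normal(0, scale, size=(rank, nd))
    J = rng.normal(0, scale, size=(rank, nc))

    if method == "svd_impute":
        U, s, Vt = np.linalg.svd(R * M, full_matrices=False)
        r = min(rank, len(s))
        I = np.zeros((rank, nd))
        J = np.zeros((rank, nc))
        I[:r] = (U[:, :r] * np.sqrt(s[:r])).T
        J[:r] = (np.sqrt(s[:r])[:, None] * Vt[:r])
        obj = masked_objective(R, M, I, J)
        return SideFactors(I, J, rank, obj, rm.drug_index, rm.cell_index,
                           history=[obj])

    history = [masked_objective(R, M, I, J)]
    if method == "als":
        lam = 1e-6
        for _ in range(iters):
            for i in range(nd):                 # solve I[:, i]
                obs = M[i] > 0
                if obs.any():
                    Jo = J[:, obs]
                    A = Jo @ Jo.T + lam * np.eye(rank)
                    I[:, i] = np.linalg.solve(A, Jo @ R[i, obs])
            for j in range(nc):
                obs = M[:, j] > 0
                if obs.any():
                    Io = I[:, obs]
                    A = Io @ Io.T + lam * np.eye(rank)
                    J[:, j] = np.linalg.solve(A, Io @ R[obs, j])
            history.append(masked_objective(R, M, I, J))
    elif method == "gd":
        step = lr
        for _ in range(iters):
            E = M * (R - I.T @ J)
            gI = -(J @ E.T)
            gJ = -(I @ E)
            # backtracking: accept the step only if the objective drops
            while True:
                In, Jn = I - step * gI, J - step * gJ
                obj = masked_objective(R, M, In, Jn)
                if obj <= history[-1] or step < 1e-12:
                    break
                step *= 0.5
            I, J = In, Jn
            history.append(obj)
            step = min(step * 1.2, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")

    return SideFactors(I, J, rank, history[-1], rm.drug_index, rm.cell_index,
                       history=history)


def _fc_apply(X: np.ndarray, layers, normalize: bool, eps: float = 1e-5):
    """Two-layer fully-connected map with optional column batch norm."""
    h = X
    for k, (W, b) in enumerate(layers):
        h = h @ np.asarray(W).T + np.asarray(b)
        if normalize:
            mu = h.mean(axis=0, keepdims=True)
            sd = np.sqrt(h.var(axis=0, keepdims=True) + eps)
            h = (h - mu) / sd
        if k < len(layers) - 1:
            h = np.where(h > 0, h, 0.01 * h)
    return h


def transform(factors: SideFactors, drug_layers, cell_layers=None,
              normalize: bool = True) -> SideInfo:
    """Map the raw factors through a fully-connected head into side info.

    ``drug_layers`` / ``cell_layers`` are lists of (W, b) pairs; with
    identity weights, zero bias and normalization disabled the output
    equals the transposed factors.
    """
    if cell_layers is None:
        cell_layers = drug_layers
    I_hat = _fc_apply(factors.I.T, drug_layers, normalize)
    J_hat = _fc_apply(factors.J.T, cell_layers, normalize)
    return SideInfo(I_hat, J_hat, factors.drug_index, factors.cell_index)


def lookup(side: SideInfo, drug_id: str, cell_id: str):
    """Fetch (i_hat, j_hat) rows; unseen ids give zeros and a cold-start flag."""
    cold = False
    if drug_id in side.drug_index:
        i_hat = side.I_hat[side.drug_index.index(drug_id)]
    else:
        i_hat = np.zeros(side.I_hat.shape[1])
        cold = True
    if cell_id in side.cell_index:
        j_hat = side.J_hat[side.cell_index.index(cell_id)]
    else:
        j_hat = np.zeros(side.J_hat.shape[1])
        cold = True
    return i_hat, j_hat, cold
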