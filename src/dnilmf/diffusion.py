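"""Nonlinear cross-diffusion of kernel pairs (similarity network fusion).

Two kernel matrices over the same entities — e.g. the interaction-profile
kernel and the chemical-structure kernel of a drug set — are fused by
iteratively propagating each one's "global" transition matrix through
the other's sparse K-nearest-neighbor graph.  The local graphs carry the
most reliable similarity signal, so after a couple of iterations strong
edges supported by either view are reinforced while weak, inconsistent
edges are suppressed.

The update rules follow the published similarity-network-fusion (SNF)
conventions: half-mass self-retention in the global transition matrix,
self-excluded KNN rows in the local affinity matrix, and a
symmetrization-plus-identity stabilization after every iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["DiffusionConfig", "global_transition", "local_affinity", "cross_diffuse"]


@dataclass
class DiffusionConfig:
    """Parameters of the cross-diffusion.

    k_neighbors
        Size of the KNN neighborhood of the local graphs (default 3).
    n_iterations
        Number of cross-diffusion steps (default 2).  Zero iterations
        returns the symmetrized average of the two global matrices.
    """

    k_neighbors: int = 3
    n_iterations: int = 2

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_iterations < 0:
            raise ValueError("n_iterations must be >= 0")


def global_transition(K: np.ndarray) -> np.ndarray:
    """Row-stochastic transition matrix retaining half the mass on self.

    ``P[i, j] = K[i, j] / (2 * sum_{l != i} K[i, l])`` off the diagonal
    and ``P[i, i] = 1/2``.  A row with no off-diagonal mass degenerates
    to the indicator at its own index.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    degenerate = row_sums == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} row(s) with no off-diagonal similarity; "
            "set to self-indicator",
            stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, row_sums)
    P = off / (2.0 * safe[:, None])
    np.fill_diagonal(P, 0.5)
    if degenerate.any():
        P[degenerate, :] = 0.0
        P[degenerate, np.flatnonzero(degenerate)] = 1.0
    return P


def local_affinity(K: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized K-nearest-neighbor affinity matrix (self excluded).

    ``L[i, j] = K[i, j] / sum_{l in N_k(i)} K[i, l]`` for j in the
    neighborhood, else 0.  Ties are broken by ascending index; if every
    neighbor similarity is zero the row falls back to uniform weights
    over the index-ordered neighbor set.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    L = np.zeros_like(K)
    for i in range(n):
        sims = K[i].copy()
        sims[i] = -np.inf
        nbrs = np.argsort(-sims, kind="stable")[:k]
        w = K[i, nbrs]
        total = w.sum()
        if total <= 0:
            warnings.warn(
                f"row {i}: all neighbor similarities zero; uniform fallback",
                stacklevel=2,
            )
            nbrs = np.sort(nbrs)
            L[i, nbrs] = 1.0 / k
        else:
            L[i, nbrs] = w / total
    return L


def _stabilize(P: np.ndarray) -> np.ndarray:
    """Symmetrize, add half identity, renormalize row-stochastic."""
    n = P.shape[0]
    P = (P + P.T) / 2.0 + np.eye(n) / 2.0
    return P / P.sum(axis=1, keepdims=True)


def cross_diffuse(
    K1: np.ndarray, K2: np.ndarray, cfg: DiffusionConfig | None = None
) -> np.ndarray:
    """Fuse two kernel matrices by iterative cross-diffusion.

    Each iteration simultaneously updates the two status matrices,
    propagating each through the other's local KNN graph:
    ``P1 <- L1 @ P2 @ L1.T`` and ``P2 <- L2 @ P1 @ L2.T`` (both from the
    previous iterates), followed by the stabilization step.  The fused
    output is the row-normalized average of the final status matrices,
    symmetrized with unit diagonal restored.
    """
    cfg = cfg or DiffusionConfig()
    K1 = np.asarray(K1, dtype=float)
    K2 = np.asarray(K2, dtype=float)
    if K1.shape != K2.shape or K1.ndim != 2 or K1.shape[0] != K1.shape[1]:
        raise ValueError(f"kernel shapes do not match: {K1.shape} vs {K2.shape}")
    L1 = local_affinity(K1, cfg.k_neighbors)
    L2 = local_affinity(K2, cfg.k_neighbors)
    P1 = global_transition(K1)
    P2 = global_transition(K2)
    for _ in range(cfg.n_iterations):
        P1_next = L1 @ P2 @ L1.T
        P2_next = L2 @ P1 @ L2.T
        P1 = _stabilize(P1_next)
        P2 = _stabilize(P2_next)
    S = (P1 + P2) / 2.0
    S = S / S.sum(axis=1, keepdims=True)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    return S
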