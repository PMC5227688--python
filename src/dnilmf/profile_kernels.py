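"""Interaction-profile inference and kernel construction.

A "new" drug (or target) is one whose row (column) of the interaction
matrix is all zero — typically an artifact of masking during
cross-validation.  Its profile is inferred as the similarity-weighted
mean of the profiles of its K most similar known neighbors.  From the
completed profile matrix the Gaussian interaction-profile (GIP) kernels
are computed, and the chemical / sequence similarity matrices are
repaired into valid (positive semidefinite) kernels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InferredInteractionMatrix",
    "find_new_entities",
    "infer_profiles",
    "gip_kernel",
    "similarity_to_kernel",
]


@dataclass
class InferredInteractionMatrix:
    """Interaction matrix with new-entity profiles filled in.

    Rows/columns not listed in ``new_drug_index`` / ``new_target_index``
    equal the corresponding rows/columns of the original binary matrix;
    inferred entries lie in [0, 1].
    """

    Yi: np.ndarray
    new_drug_index: frozenset[int] = field(default_factory=frozenset)
    new_target_index: frozenset[int] = field(default_factory=frozenset)


def find_new_entities(Y: np.ndarray) -> tuple[frozenset[int], frozenset[int]]:
    """Indices of all-zero rows (new drugs) and columns (new targets)."""
    Y = np.asarray(Y)
    new_drugs = frozenset(np.flatnonzero(Y.sum(axis=1) == 0).tolist())
    new_targets = frozenset(np.flatnonzero(Y.sum(axis=0) == 0).tolist())
    return new_drugs, new_targets


def _knn_weighted_profiles(
    Y: np.ndarray, S: np.ndarray, new_idx: frozenset[int], K: int
) -> np.ndarray:
    """Row profiles for ``new_idx`` as weighted means over KNN rows of Y.

    The neighbor pool excludes self and other new entities.  Ties in
    similarity are broken by ascending index (stable sort).
    """
    n = Y.shape[0]
    known = np.array(sorted(set(range(n)) - new_idx), dtype=int)
    out = np.zeros((len(new_idx), Y.shape[1]))
    for row, i in enumerate(sorted(new_idx)):
        if known.size == 0:
            warnings.warn(f"entity {i}: no known neighbors available", stacklevel=3)
            continue
        sims = S[i, known]
        # stable sort on -sims keeps ascending-index order among ties
        order = np.argsort(-sims, kind="stable")[:K]
        nbrs = known[order]
        w = S[i, nbrs]
        total = w.sum()
        if total <= 0:
            warnings.warn(
                f"entity {i}: all neighbor similarities zero; profile left zero",
                stacklevel=3,
            )
            continue
        out[row] = w @ Y[nbrs] / total
    return out


def infer_profiles(
    Y: np.ndarray, S_cs: np.ndarray, S_ts: np.ndarray, K: int = 5
) -> InferredInteractionMatrix:
    """Fill all-zero rows/columns of Y from nearest-neighbor profiles.

    For a new drug i the inferred row is
    ``sum_u S_cs[i,u] * Y[u,:] / sum_u S_cs[i,u]`` over its K most
    similar known drugs; new targets are handled symmetrically on
    columns with ``S_ts``.  Known rows and columns are untouched, which
    also makes the operation idempotent.
    """
    Y = np.asarray(Y, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    new_drugs, new_targets = find_new_entities(Y)
    Yi = Y.copy()
    if new_drugs:
        rows = _knn_weighted_profiles(Y, S_cs, new_drugs, K)
        Yi[sorted(new_drugs), :] = rows
    if new_targets:
        cols = _knn_weighted_profiles(Y.T, S_ts, new_targets, K)
        Yi[:, sorted(new_targets)] = cols.T
    return InferredInteractionMatrix(
        Yi=Yi, new_drug_index=new_drugs, new_target_index=new_targets
    )


def gip_kernel(Yi: np.ndarray, axis: str = "drugs") -> np.ndarray:
    """Gaussian interaction-profile kernel over rows or columns of Yi.

    ``K[i, j] = exp(-gamma * ||y_i - y_j||^2)`` with the bandwidth set
    by the mean squared profile norm, ``gamma = n / sum_i ||y_i||^2``.
    This makes the kernel invariant to a global rescaling of the
    profiles.
    """
    Yi = np.asarray(Yi, dtype=float)
    profiles = Yi if axis == "drugs" else Yi.T
    if axis not in ("drugs", "targets"):
        raise ValueError(f"axis must be 'drugs' or 'targets', got {axis!r}")
    sq_norms = (profiles**2).sum(axis=1)
    total = sq_norms.sum()
    if total == 0:
        raise ValueError("all interaction profiles are zero; bandwidth undefined")
    gamma = profiles.shape[0] / total
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def similarity_to_kernel(S: np.ndarray, psd_repair: bool = True) -> np.ndarray:
    """Turn a similarity matrix into a valid kernel matrix.

    The matrix is symmetrized and given a unit diagonal; if it is not
    positive semidefinite it is repaired by clipping negative
    eigenvalues at zero and rescaling the diagonal back to 1.  A matrix
    that is already PSD passes through unchanged.  Set
    ``psd_repair=False`` for plain symmetrize-and-unit-diagonal
    pass-through.
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"similarity matrix must be square, got {S.shape}")
    K = (S + S.T) / 2.0
    np.fill_diagonal(K, 1.0)
    if not psd_repair:
        return K
    eigvals, eigvecs = np.linalg.eigh(K)
    if eigvals.min(initial=0.0) >= -1e-10:
        return K
    eigvals = np.clip(eigvals, 0.0, None)
    K = (eigvecs * eigvals) @ eigvecs.T
    d = np.sqrt(np.clip(np.diag(K), 1e-12, None))
    K = K / np.outer(d, d)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    if K.min() < -1e-8:
        warnings.warn(
            "PSD repair produced negative similarities; clipped to 0", stacklevel=2
        )
    np.clip(K, 0.0, 1.0, out=K)
    return K
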