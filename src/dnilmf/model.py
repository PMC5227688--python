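"""Dual-network integrated logistic matrix factorization (DNILMF).

The model scores a drug-target pair through a logistic link applied to
a linear predictor that mixes the latent factorization with the two
fused similarity networks:

    x = alpha * U V' + beta * S_d U V' + gamma * U V' S_t

with alpha + beta + gamma = 1.  Observed interactions are up-weighted
c-fold in the Bernoulli likelihood to counter the extreme class
imbalance of interaction matrices, and zero-mean spherical Gaussian
priors on the latent vectors contribute Frobenius-norm penalties
lambda_u, lambda_v.  U and V are found by AdaGrad gradient ascent on
the penalized log-likelihood.  After fitting, the latent vectors of new
(all-zero-profile) drugs or targets are replaced by similarity-weighted
means of their nearest known neighbors in the fused networks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import PredictionTable

__all__ = [
    "Hyperparams",
    "DNILMFModel",
    "linear_predictor",
    "interaction_probability",
    "log_likelihood",
    "gradients",
    "fit",
    "smooth_new_entities",
    "predict",
    "predict_pairs",
    "save_model",
    "load_model",
]


@dataclass
class Hyperparams:
    """DNILMF hyperparameters with the model's empirical defaults.

    num_latent
        Latent dimension r of U and V.
    c
        Augmentation weight (>= 1) on observed interactions.
    alpha, beta, gamma
        Mixing coefficients of the linear predictor; must sum to 1.
        beta weighs the drug network term, gamma the target network term.
    lambda_u, lambda_v
        Gaussian-prior (L2) penalties on U and V.
    k_smooth
        Neighbor count for profile inference and latent smoothing.
    learn_rate, max_iter
        AdaGrad step size and number of ascent iterations.
    """

    num_latent: int = 50
    c: float = 5.0
    alpha: float = 0.5
    beta: float = 0.25
    gamma: float = 0.25
    lambda_u: float = 5.0
    lambda_v: float = 1.0
    k_smooth: int = 5
    learn_rate: float = 0.1
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.alpha + self.beta + self.gamma - 1.0) > 1e-12:
            raise ValueError("alpha + beta + gamma must equal 1")
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("mixing coefficients must be nonnegative")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.num_latent < 1:
            raise ValueError("num_latent must be >= 1")
        if self.learn_rate <= 0:
            raise ValueError("learn_rate must be positive")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class DNILMFModel:
    """A fitted (or in-progress) DNILMF model."""

    U: np.ndarray
    V: np.ndarray
    S_d: np.ndarray
    S_t: np.ndarray
    hyper: Hyperparams
    fitted: bool = False
    ll_trace: list[float] = field(default_factory=list)


def linear_predictor(
    U: np.ndarray,
    V: np.ndarray,
    S_d: np.ndarray,
    S_t: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
) -> np.ndarray:
    """Network-mixed logits: alpha*UV' + beta*S_d UV' + gamma*UV' S_t."""
    UVt = U @ V.T
    return alpha * UVt + beta * (S_d @ UVt) + gamma * (UVt @ S_t)


def interaction_probability(x: np.ndarray) -> np.ndarray:
    """Overflow-safe logistic transform of the logits."""
    # scipy.special.expit is equivalent; the piecewise form keeps the
    # model module dependency-light and is exact for |x| up to ~745
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log1pexp(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def log_likelihood(
    Y: np.ndarray,
    x: np.ndarray,
    c: float,
    lambda_u: float,
    lambda_v: float,
    U: np.ndarray,
    V: np.ndarray,
) -> float:
    """Penalized augmented Bernoulli log-likelihood.

    LL = sum_ij [ c Y x - (1 + c Y - Y) log(1 + e^x) ]
         - lambda_u/2 ||U||_F^2 - lambda_v/2 ||V||_F^2
    """
    weights = 1.0 + c * Y - Y
    ll = float(np.sum(c * Y * x - weights * _log1pexp(x)))
    ll -= 0.5 * lambda_u * float(np.sum(U**2))
    ll -= 0.5 * lambda_v * float(np.sum(V**2))
    return ll


def gradients(
    Y: np.ndarray,
    U: np.ndarray,
    V: np.ndarray,
    S_d: np.ndarray,
    S_t: np.ndarray,
    hyper: Hyperparams,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic ascent gradients of the penalized log-likelihood.

    With P the predicted probabilities and the residual-like matrix
    Q = c Y - (1 + c Y - Y) o P:

        dU = (alpha I + beta S_d') Q V + gamma Q S_t' V - lambda_u U
        dV = Q' (alpha I + beta S_d) U + gamma S_t' Q' U - lambda_v V
    """
    a, b, g = hyper.alpha, hyper.beta, hyper.gamma
    x = linear_predictor(U, V, S_d, S_t, a, b, g)
    P = interaction_probability(x)
    Q = hyper.c * Y - (1.0 + hyper.c * Y - Y) * P
    dU = a * (Q @ V) + b * (S_d.T @ (Q @ V)) + g * ((Q @ S_t.T) @ V) - hyper.lambda_u * U
    dV = a * (Q.T @ U) + b * (Q.T @ (S_d @ U)) + g * (S_t.T @ (Q.T @ U)) - hyper.lambda_v * V
    return dU, dV


def _init_latents(
    n_drugs: int, n_targets: int, r: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_drugs, r)) / np.sqrt(r)
    V = rng.standard_normal((n_targets, r)) / np.sqrt(r)
    return U, V


def fit(
    Y_train: np.ndarray,
    S_d: np.ndarray,
    S_t: np.ndarray,
    hyper: Hyperparams | None = None,
) -> DNILMFModel:
    """Fit U, V by AdaGrad gradient ascent; deterministic given the seed.

    Latents are initialized from a seeded standard normal scaled by
    1/sqrt(r).  Per-element squared gradients are accumulated and the
    update is ``learn_rate * g / sqrt(G + 1e-8)``.  Both latent matrices
    are updated simultaneously from the current iterate.
    """
    hyper = hyper or Hyperparams()
    Y = np.asarray(Y_train, dtype=float)
    n_d, n_t = Y.shape
    r = hyper.num_latent
    U, V = _init_latents(n_d, n_t, r, hyper.seed)
    G_u = np.zeros_like(U)
    G_v = np.zeros_like(V)
    eps = 1e-8
    trace: list[float] = []
    for it in range(hyper.max_iter):
        dU, dV = gradients(Y, U, V, S_d, S_t, hyper)
        G_u += dU**2
        G_v += dV**2
        U = U + hyper.learn_rate * dU / np.sqrt(G_u + eps)
        V = V + hyper.learn_rate * dV / np.sqrt(G_v + eps)
        x = linear_predictor(U, V, S_d, S_t, hyper.alpha, hyper.beta, hyper.gamma)
        ll = log_likelihood(Y, x, hyper.c, hyper.lambda_u, hyper.lambda_v, U, V)
        if not np.isfinite(ll):
            raise FloatingPointError(
                f"objective became non-finite at iteration {it + 1}"
            )
        trace.append(ll)
    return DNILMFModel(
        U=U, V=V, S_d=S_d, S_t=S_t, hyper=hyper, fitted=True, ll_trace=trace
    )


def _smooth_rows(
    M: np.ndarray, S: np.ndarray, new_idx: frozenset[int], K: int
) -> np.ndarray:
    """Replace rows of M in ``new_idx`` by KNN similarity-weighted means."""
    n = M.shape[0]
    known = np.array(sorted(set(range(n)) - set(new_idx)), dtype=int)
    out = M.copy()
    for i in sorted(new_idx):
        if known.size == 0:
            warnings.warn(f"entity {i}: no eligible neighbors; latent row kept",
                          stacklevel=3)
            continue
        sims = S[i, known]
        order = np.argsort(-sims, kind="stable")[:K]
        nbrs = known[order]
        w = S[i, nbrs]
        total = w.sum()
        if total <= 0:
            warnings.warn(
                f"entity {i}: zero similarity to all neighbors; latent row kept",
                stacklevel=3,
            )
            continue
        out[i] = w @ M[nbrs] / total
    return out


def smooth_new_entities(
    model: DNILMFModel,
    new_drugs: frozenset[int] | set[int],
    new_targets: frozenset[int] | set[int],
) -> DNILMFModel:
    """Replace latent rows of new entities by fused-network neighbor means.

    For a new drug i, ``U_i <- sum_u S_d[i,u] U_u / sum_u S_d[i,u]``
    over its k_smooth most similar known drugs; symmetrically for new
    targets with S_t and V.  Returns a new model; the input is unchanged.
    """
    if not model.fitted:
        raise RuntimeError("model must be fitted before smoothing")
    K = model.hyper.k_smooth
    U = _smooth_rows(model.U, model.S_d, frozenset(new_drugs), K)
    V = _smooth_rows(model.V, model.S_t, frozenset(new_targets), K)
    return replace(model, U=U, V=V)


def predict(model: DNILMFModel) -> np.ndarray:
    """Interaction probability matrix for every drug-target pair."""
    if not model.fitted:
        raise RuntimeError("model is not fitted")
    h = model.hyper
    x = linear_predictor(model.U, model.V, model.S_d, model.S_t,
                         h.alpha, h.beta, h.gamma)
    return interaction_probability(x)


def predict_pairs(
    model: DNILMFModel,
    pairs: list[tuple[int, int]],
    drug_ids: list[str],
    target_ids: list[str],
    Y: np.ndarray,
) -> PredictionTable:
    """Score the given (drug index, target index) pairs as a ranked table."""
    P = predict(model)
    return PredictionTable.from_scores(
        drug_ids=[drug_ids[i] for i, _ in pairs],
        target_ids=[target_ids[j] for _, j in pairs],
        scores=[P[i, j] for i, j in pairs],
        known=[bool(Y[i, j]) for i, j in pairs],
    )


CHECKPOINT_VERSION = 1


def save_model(
    model: DNILMFModel,
    path: str,
    drug_ids: list[str] | None = None,
    target_ids: list[str] | None = None,
) -> None:
    """Save a model checkpoint (single .npz archive plus a JSON header)."""
    meta = {
        "version": CHECKPOINT_VERSION,
        "hyper": model.hyper.to_dict(),
        "fitted": model.fitted,
        "drug_ids": drug_ids,
        "target_ids": target_ids,
    }
    with open(path, "wb") as fh:
        np.savez(
            fh,
            U=model.U,
            V=model.V,
            S_d=model.S_d,
            S_t=model.S_t,
            ll_trace=np.asarray(model.ll_trace),
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        )


def load_model(path: str) -> tuple[DNILMFModel, dict]:
    """Load a checkpoint; returns ``(model, metadata)``."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        model = DNILMFModel(
            U=data["U"],
            V=data["V"],
            S_d=data["S_d"],
            S_t=data["S_t"],
            hyper=Hyperparams(**meta["hyper"]),
            fitted=bool(meta["fitted"]),
            ll_trace=[float(v) for v in data["ll_trace"]],
        )
    return model, meta
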