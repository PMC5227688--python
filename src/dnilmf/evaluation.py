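"""Cross-validation protocol and ranking metrics.

Three fold constructions are supported, mirroring the standard DTI
evaluation settings:

* CVP — folds over drug-target *pairs* (cells of Y); measures filling
  in missing entries of a partially observed network.
* CVR — folds over *rows* (drugs); every held-out drug becomes a new
  drug with its entire interaction profile hidden.
* CVC — folds over *columns* (targets); the symmetric new-target case.

Within each fold the full pipeline — profile inference, kernel
construction, diffusion, model fitting and neighbor smoothing — is
recomputed from the masked training matrix, so no information from the
held-out cells can leak into the kernels.  Held-out cells are pooled
per fold for AUC/AUPR, which keeps both metrics well defined even when
an individual row or column is single-class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score

from .data_io import DTIDataset, PredictionTable
from .diffusion import DiffusionConfig, cross_diffuse
from .model import (
    DNILMFModel,
    Hyperparams,
    fit,
    predict,
    smooth_new_entities,
)
from .profile_kernels import (
    find_new_entities,
    gip_kernel,
    infer_profiles,
    similarity_to_kernel,
)

__all__ = [
    "CVFoldPlan",
    "CVResult",
    "make_folds",
    "auc",
    "aupr",
    "run_pipeline_fold",
    "run_cv",
    "rank_novel",
]

SETTINGS = ("CVP", "CVR", "CVC")


@dataclass
class CVFoldPlan:
    """One train/test split: held-out cells and the masked training matrix."""

    setting: str
    trial: int
    fold: int
    test_cells: list[tuple[int, int]]
    Y_train: np.ndarray


@dataclass
class CVResult:
    """Per-fold metrics and their aggregates over the full fold set."""

    setting: str
    fold_aupr: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)
    skipped_folds: int = 0

    @property
    def mean_aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def sd_aupr(self) -> float:
        return float(np.std(self.fold_aupr, ddof=1)) if len(self.fold_aupr) > 1 else 0.0

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "setting": self.setting,
            "n_folds": len(self.fold_aupr),
            "skipped_folds": self.skipped_folds,
            "aupr_mean": self.mean_aupr,
            "aupr_sd": self.sd_aupr,
            "auc_mean": self.mean_auc,
            "auc_sd": self.sd_auc,
            "fold_aupr": self.fold_aupr,
            "fold_auc": self.fold_auc,
        }


def make_folds(
    Y: np.ndarray,
    setting: str,
    n_folds: int = 10,
    n_trials: int = 5,
    seed: int = 0,
) -> list[CVFoldPlan]:
    """Build the fold plans for one CV setting.

    CVP shuffles all cells into near-equal parts; CVR/CVC shuffle rows
    or columns, a fold's test cells being every cell of its held-out
    rows/columns.  Per-trial seeds are derived as ``seed + trial`` so
    trials are reproducible yet distinct.
    """
    Y = np.asarray(Y, dtype=float)
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}, got {setting!r}")
    n_d, n_t = Y.shape
    if Y.size == 0:
        raise ValueError("empty interaction matrix")
    if setting == "CVP":
        n_units = n_d * n_t
    elif setting == "CVR":
        n_units = n_d
    else:
        n_units = n_t
    if n_folds > n_units:
        raise ValueError(f"n_folds={n_folds} exceeds number of split units {n_units}")
    plans: list[CVFoldPlan] = []
    for trial in range(n_trials):
        rng = np.random.default_rng(seed + trial)
        perm = rng.permutation(n_units)
        parts = np.array_split(perm, n_folds)
        for fold, part in enumerate(parts):
            if setting == "CVP":
                cells = [(int(u) // n_t, int(u) % n_t) for u in part]
            elif setting == "CVR":
                cells = [(int(u), j) for u in part for j in range(n_t)]
            else:
                cells = [(i, int(u)) for u in part for i in range(n_d)]
            Y_train = Y.copy()
            idx = tuple(np.array(cells).T)
            Y_train[idx] = 0.0
            plans.append(
                CVFoldPlan(
                    setting=setting,
                    trial=trial,
                    fold=fold,
                    test_cells=cells,
                    Y_train=Y_train,
                )
            )
    return plans


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC = P(score_pos > score_neg), ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, scores))


def aupr(labels: np.ndarray, scores: np.ndarray, interpolate: bool = False) -> float:
    """Area under the precision-recall curve.

    The default is the step-wise sum over descending-score thresholds,
    ``sum_k (R_k - R_{k-1}) P_k`` (identical to average precision);
    ``interpolate=True`` instead integrates the PR curve with the
    trapezoid rule, which reads slightly higher on coarse curves.
    """
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined: no positives present")
    if not interpolate:
        return float(average_precision_score(labels, scores))
    precision, recall, _ = precision_recall_curve(labels, scores)
    return float(np.trapezoid(precision[::-1], recall[::-1]))


def run_pipeline_fold(
    Y_train: np.ndarray,
    S_cs: np.ndarray,
    S_ts: np.ndarray,
    hyper: Hyperparams,
    diff_cfg: DiffusionConfig,
    smoothing: bool = True,
) -> DNILMFModel:
    """Run the full four-step pipeline on one training matrix.

    Profile inference -> GIP + structure/sequence kernels -> diffusion
    -> DNILMF fit -> neighbor smoothing of new entities.  Everything is
    derived from ``Y_train`` only.
    """
    inferred = infer_profiles(Y_train, S_cs, S_ts, K=hyper.k_smooth)
    K_d = gip_kernel(inferred.Yi, axis="drugs")
    K_t = gip_kernel(inferred.Yi, axis="targets")
    K_c = similarity_to_kernel(S_cs)
    K_p = similarity_to_kernel(S_ts)
    S_d = cross_diffuse(K_d, K_c, diff_cfg)
    S_t = cross_diffuse(K_t, K_p, diff_cfg)
    model = fit(Y_train, S_d, S_t, hyper)
    if smoothing:
        new_drugs, new_targets = find_new_entities(Y_train)
        if new_drugs or new_targets:
            model = smooth_new_entities(model, new_drugs, new_targets)
    return model


def run_cv(
    ds: DTIDataset,
    hyper: Hyperparams | None = None,
    setting: str = "CVP",
    diff_cfg: DiffusionConfig | None = None,
    n_folds: int = 10,
    n_trials: int = 5,
    seed: int = 0,
    smoothing: bool = True,
) -> CVResult:
    """Cross-validate the full pipeline under one setting.

    Held-out cells are scored against the original Y, pooled per fold;
    a fold whose evaluation set is single-class is skipped with a
    warning and recorded in the result.
    """
    hyper = hyper or Hyperparams()
    diff_cfg = diff_cfg or DiffusionConfig()
    if ds.S_cs is None or ds.S_ts is None:
        raise ValueError("dataset must carry both similarity matrices")
    result = CVResult(setting=setting)
    plans = make_folds(ds.Y, setting, n_folds=n_folds, n_trials=n_trials, seed=seed)
    for plan in plans:
        fold_hyper = Hyperparams(
            **{**hyper.to_dict(), "seed": hyper.seed + 1000 * plan.trial + plan.fold}
        )
        model = run_pipeline_fold(
            plan.Y_train, ds.S_cs, ds.S_ts, fold_hyper, diff_cfg, smoothing=smoothing
        )
        P = predict(model)
        idx = tuple(np.array(plan.test_cells).T)
        labels = ds.Y[idx]
        scores = P[idx]
        if len(np.unique(labels)) < 2:
            warnings.warn(
                f"{setting} trial {plan.trial} fold {plan.fold}: "
                "single-class evaluation set; skipped",
                stacklevel=2,
            )
            result.skipped_folds += 1
            continue
        result.fold_auc.append(auc(labels, scores))
        result.fold_aupr.append(aupr(labels, scores))
    return result


def rank_novel(model: DNILMFModel, ds: DTIDataset, top_n: int) -> PredictionTable:
    """Rank unobserved (Y=0) pairs by predicted score, keep the top_n."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    P = predict(model)
    zero_cells = np.argwhere(ds.Y == 0)
    table = PredictionTable.from_scores(
        drug_ids=[ds.drug_ids[i] for i, _ in zero_cells],
        target_ids=[ds.target_ids[j] for _, j in zero_cells],
        scores=[P[i, j] for i, j in zero_cells],
        known=[False] * len(zero_cells),
    )
    table.records = table.records[:top_n]
    return table
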