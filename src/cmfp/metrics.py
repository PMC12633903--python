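"""Evaluation battery: AUC, confusion metrics, error metrics, bootstrap
ROC bands, Mann-Whitney U comparisons, k-fold learner comparison and
repeated-run summaries.

AUC is the probability that a randomly drawn positive outscores a randomly
drawn negative, ties counted one half (equivalently the trapezoidal area
under the ROC curve); MAE and RMSE are computed on predicted probabilities
against the 0/1 outcome. Repeated-run variances are population variances
(divide by the number of runs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetricsReport",
    "RunSummary",
    "RocBand",
    "roc_auc",
    "confusion_metrics",
    "error_metrics",
    "evaluate_predictions",
    "roc_curve_ci",
    "mann_whitney_u",
    "kfold_compare",
    "repeated_run_summary",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts plus the derived scalar metrics for one prediction set."""

    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    acc: float
    sen: float
    spe: float
    f1: float
    auc: float = float("nan")
    mae: float = float("nan")
    rmse: float = float("nan")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("n", "tp", "fp", "tn", "fn", "acc", "sen", "spe", "f1",
                      "auc", "mae", "rmse")
        }


@dataclass(frozen=True)
class RunSummary:
    """Mean and population variance of one metric over repeated runs."""

    metric: str
    values: tuple[float, ...]
    mean: float
    variance: float


@dataclass(frozen=True)
class RocBand:
    """Pointwise bootstrap band around a ROC curve on a common FPR grid."""

    fpr: np.ndarray
    tpr: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    auc: float
    level: float


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic form, ties = 1/2)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def confusion_metrics(pred_labels, labels) -> MetricsReport:
    """ACC / SEN / SPE / F1 from the 2x2 confusion table.

    A sensitivity, specificity or F1 whose denominator is empty is NaN.
    """
    rho = np.asarray(pred_labels, dtype=int)
    y = np.asarray(labels, dtype=int)
    if len(rho) != len(y):
        raise ValueError("prediction and label lengths differ")
    if len(y) == 0:
        raise ValueError("empty input")
    tp = int(np.sum((rho == 1) & (y == 1)))
    fp = int(np.sum((rho == 1) & (y == 0)))
    tn = int(np.sum((rho == 0) & (y == 0)))
    fn = int(np.sum((rho == 0) & (y == 1)))
    n = len(y)

    def _ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return MetricsReport(
        n=n, tp=tp, fp=fp, tn=tn, fn=fn,
        acc=(tp + tn) / n,
        sen=_ratio(tp, tp + fn),
        spe=_ratio(tn, tn + fp),
        f1=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def error_metrics(probabilities, labels) -> tuple[float, float]:
    """(MAE, RMSE) of predicted probabilities against the 0/1 outcome."""
    eta = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if eta.shape != y.shape:
        raise ValueError("probability and label lengths differ")
    err = eta - y
    return float(np.mean(np.abs(err))), float(np.sqrt(np.mean(err**2)))


def evaluate_predictions(pred_labels, probabilities, labels) -> MetricsReport:
    """Full report: confusion metrics + AUC + MAE/RMSE.

    AUC is NaN when only one class is present in ``labels``.
    """
    base = confusion_metrics(pred_labels, labels)
    mae, rmse = error_metrics(probabilities, labels)
    y = np.asarray(labels, dtype=int)
    auc = (
        roc_auc(probabilities, y) if len(np.unique(y)) == 2 else float("nan")
    )
    return MetricsReport(**{**base.to_dict(), "auc": auc, "mae": mae, "rmse": rmse})


def roc_curve_ci(
    scores,
    labels,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    grid_size: int = 101,
) -> RocBand:
    """Pointwise percentile bootstrap band for the ROC curve.

    Bootstrap resampling is stratified (within class), so every resample
    contains both classes and has a defined curve. Curves are compared on
    a common false-positive-rate grid by linear interpolation.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile band")
    eta = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC band needs both classes present")
    grid = np.linspace(0.0, 1.0, grid_size)
    fpr, tpr, _ = roc_curve(y, eta)
    point = np.interp(grid, fpr, tpr)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, grid_size))
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
        )
        f, t, _ = roc_curve(y[idx], eta[idx])
        boots[b] = np.interp(grid, f, t)
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(boots, alpha, axis=0)
    upper = np.quantile(boots, 1.0 - alpha, axis=0)
    return RocBand(
        fpr=grid, tpr=point, lower=lower, upper=upper,
        auc=roc_auc(eta, y), level=level,
    )


def mann_whitney_u(sample_a, sample_b) -> tuple[float, float]:
    """Mann-Whitney U (for sample_a) with a two-sided p-value.

    The p-value is exact (full enumeration) when ``n_a * n_b <= 400`` and
    the pooled data are tie-free, otherwise the normal approximation with
    tie correction and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(a) * len(b) <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kfold_compare(
    cohort,
    learners=None,
    k: int = 8,
    seed: int = 0,
    epochs: int = 10,
    pair: tuple[str, str] = ("clinical", "dti"),
    n_estimators: int = 50,
) -> pd.DataFrame:
    """Stratified k-fold comparison of base learners inside the full pipeline.

    For every registered base learner, each fold's training portion goes
    through the complete protocol — repeated resplits, per-epoch lasso
    selection, per-modality fits, best-model tracking — with that learner
    substituted for the boosted stumps, and the fold's held-out portion is
    scored through the fusion rule. Rows are per-learner metric means over
    the k folds.
    """
    from .learners import BASE_LEARNERS
    from .training import TrainConfig, fit_cmfp, test_cmfp

    names = list(learners) if learners is not None else list(BASE_LEARNERS)
    y = cohort.labels
    if np.bincount(y).min() < k:
        raise ValueError(
            f"k={k} exceeds the smaller class size {int(np.bincount(y).min())}; "
            "reduce k or enlarge the cohort"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    ids = np.asarray(cohort.patient_ids, dtype=object)
    rows = []
    for name in names:
        fold_reports = []
        for fold, (tr, te) in enumerate(skf.split(ids, y)):
            sub = cohort.subset(list(ids[tr]))
            config = TrainConfig(
                pair=pair,
                epochs=epochs,
                fractions=(0.6, 0.3, 0.0),
                master_seed=seed * 1000 + fold,
                n_estimators=n_estimators,
                base_learner=name,
            )
            archive = fit_cmfp(sub, config)
            _, report = test_cmfp(archive, cohort.subset(list(ids[te])))
            fold_reports.append(report.to_dict())
        mean = pd.DataFrame(fold_reports).mean(numeric_only=True)
        mean.name = name
        rows.append(mean)
    table = pd.DataFrame(rows)
    table.index.name = "learner"
    return table[["auc", "acc", "sen", "spe", "f1", "mae", "rmse"]]


def repeated_run_summary(values, metric: str = "metric") -> RunSummary:
    """Mean and population variance over repeated runs (needs >= 2 runs)."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 runs to summarise")
    return RunSummary(
        metric=metric,
        values=tuple(float(x) for x in v),
        mean=float(np.mean(v)),
        variance=float(np.var(v)),  # population variance
    )
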