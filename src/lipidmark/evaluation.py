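"""Splitting, confusion metrics, ROC/PR areas, bootstrap CIs, χ² check.

All metrics are reported as percents. Confidence intervals are
percentile bootstrap intervals: the test set is resampled with
replacement within each class, the metric recomputed, and the
2.5th/97.5th percentiles taken as order statistics of the resample
vector. For hard (0/1) predictions the ROC area equals the balanced
accuracy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .cohort import diagnosis_vector

__all__ = [
    "stratified_split",
    "confusion_metrics",
    "roc_pr_areas",
    "bootstrap_ci",
    "performance_report",
    "sex_balance_chisq",
]

METRIC_NAMES = (
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "balanced_accuracy",
    "auc_roc",
    "auprc",
)


def stratified_split(
    cohort: pd.DataFrame, train_fraction: float = 2 / 3, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Class-proportional train/test split of a cohort table.

    Per class, round-half-up of ``train_fraction`` × class size rows go
    to the training side; the split is disjoint and exhaustive.
    (102 patients / 301 controls at 2/3 → train 68/201, test 34/100.)
    """
    y = diagnosis_vector(cohort)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in (1, 0):
        idx = np.flatnonzero(y == cls)
        if len(idx) < 3:
            raise ValueError("each class needs at least 3 subjects to split")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        if n_train >= len(idx):
            raise ValueError("train fraction leaves an empty test set")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = cohort.iloc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test = cohort.iloc[np.sort(np.concatenate(test_idx))].reset_index(drop=True)
    return train, test


def confusion_metrics(truth, predicted) -> dict[str, float]:
    """Confusion-matrix test performance measures, in percent.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    ppv = TP/(TP+FP), npv = TN/(TN+FN),
    balanced accuracy = (sensitivity + specificity)/2.
    A metric with an empty denominator is reported as NaN.
    """
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction must have equal length")
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    tp = int(((truth == 1) & (predicted == 1)).sum())
    fn = int(((truth == 1) & (predicted == 0)).sum())
    tn = int(((truth == 0) & (predicted == 0)).sum())
    fp = int(((truth == 0) & (predicted == 1)).sum())

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "balanced_accuracy": (sens + spec) / 2,
    }


def roc_pr_areas(scores, truth) -> dict[str, float]:
    """ROC and precision-recall areas (percent).

    Trapezoidal ROC area (equivalently the tie-aware pairwise
    concordance probability); PR area as average precision (step-wise
    precision interpolation over recall levels). Binary 0/1 scores are
    allowed, in which case auc_roc = (sensitivity + specificity)/2.
    """
    truth = np.asarray(truth).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(truth)) < 2:
        raise ValueError("truth must contain both classes")
    return {
        "auc_roc": 100.0 * float(roc_auc_score(truth, scores)),
        "auprc": 100.0 * float(average_precision_score(truth, scores)),
    }


def bootstrap_ci(
    metric_fn,
    truth,
    values,
    n_resamples: int = 1000,
    seed: int = 0,
    ci: tuple[float, float] = (2.5, 97.5),
) -> tuple[float, float, np.ndarray, int]:
    """Stratified percentile bootstrap CI for one metric.

    ``metric_fn(truth, values) -> float`` is recomputed on
    ``n_resamples`` within-class resamples (with replacement);
    resamples yielding NaN are dropped and counted. Returns
    (low, high, resample values, n_dropped); the endpoints are order
    statistics of the resample vector (index ceil(q·n) − 1).
    """
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    truth = np.asarray(truth).astype(int)
    values = np.asarray(values)
    rng = np.random.default_rng(seed)
    idx_pos = np.flatnonzero(truth == 1)
    idx_neg = np.flatnonzero(truth == 0)
    out = np.empty(n_resamples)
    for b in range(n_resamples):
        take = np.concatenate(
            [
                rng.choice(idx_pos, len(idx_pos), replace=True),
                rng.choice(idx_neg, len(idx_neg), replace=True),
            ]
        )
        out[b] = metric_fn(truth[take], values[take])
    kept = out[~np.isnan(out)]
    n_dropped = int(np.isnan(out).sum())
    if kept.size == 0:
        raise ValueError("metric undefined on every bootstrap resample")
    ordered = np.sort(kept)
    lo = ordered[max(int(np.ceil(ci[0] / 100 * kept.size)) - 1, 0)]
    hi = ordered[max(int(np.ceil(ci[1] / 100 * kept.size)) - 1, 0)]
    return float(lo), float(hi), out, n_dropped


@dataclass
class PerformanceReport:
    """Point estimates with bootstrap CIs for the seven test measures."""

    point: dict[str, float]
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    n_bootstrap: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in METRIC_NAMES:
            rows.append(
                {
                    "metric": m,
                    "point": self.point.get(m, float("nan")),
                    "ci_low": self.ci_low.get(m, float("nan")),
                    "ci_high": self.ci_high.get(m, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def _metric_closure(name):
    if name in ("auc_roc", "auprc"):
        def fn(t, v):
            try:
                return roc_pr_areas(v, t)[name]
            except ValueError:
                return float("nan")
    else:
        def fn(t, v):
            try:
                return confusion_metrics(t, (np.asarray(v) >= 0.5).astype(int))[name]
            except ValueError:
                return float("nan")
    return fn


def performance_report(
    truth,
    predicted,
    scores=None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> PerformanceReport:
    """Full report: confusion metrics on hard predictions, areas on
    scores (predictions reused when no scores are available), each with
    a stratified percentile bootstrap CI on shared resampling seeds."""
    truth = np.asarray(truth).astype(int)
    predicted = np.asarray(predicted).astype(int)
    if scores is None:
        scores = predicted.astype(float)
    scores = np.asarray(scores, dtype=float)
    point = confusion_metrics(truth, predicted)
    point.update(roc_pr_areas(scores, truth))
    report = PerformanceReport(point=point, n_bootstrap=n_bootstrap)
    for name in METRIC_NAMES:
        vals = scores if name in ("auc_roc", "auprc") else predicted
        lo, hi, _, _ = bootstrap_ci(
            _metric_closure(name), truth, vals, n_resamples=n_bootstrap, seed=seed
        )
        report.ci_low[name] = lo
        report.ci_high[name] = hi
    return report


def sex_balance_chisq(
    n_male_a: int, n_female_a: int, n_male_b: int, n_female_b: int
) -> tuple[float, int, float]:
    """Pearson χ² with Yates continuity correction for a 2×2 sex-by-group
    table; the |O − E| − 0.5 correction is floored at 0 so a perfectly
    proportional table scores exactly 0. Returns (χ², df=1, p)."""
    obs = np.array([[n_male_a, n_female_a], [n_male_b, n_female_b]], dtype=float)
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    if obs.sum() == 0:
        raise ValueError("table total must be positive")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero marginal in the 2x2 table")
    expected = row * col / obs.sum()
    chi2 = float(((np.clip(np.abs(obs - expected) - 0.5, 0, None)) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, 1, p
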