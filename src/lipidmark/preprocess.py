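"""Preprocessing: outlier screening, age/sex correction, transforms.

The stage order used by the pipeline is fixed: Grubbs outlier scan →
age/sex confound correction → zero-invariant log transform ln(x+1) →
per-feature percent normalization (the last only for distance-based
structure mapping, not for classifier fitting).

The correction applied to each marker column is

    corrected = original + (age − reference_age) · age_slope
                − (median sex difference if male else 0)

with ``age_slope`` the *correction* slope (the negated OLS trend of
concentration on age, so that applying the formula removes the trend),
``median sex difference`` = median(male) − median(female), and
``reference_age`` the minimum age of the fitting cohort. Corrected
values may be negative; ln(x+1) is defined there and no clamping rule
is imposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cohort import marker_columns

__all__ = [
    "OutlierReport",
    "grubbs_scan",
    "grubbs_critical_value",
    "ConfoundCorrector",
    "fit_correction",
    "apply_correction",
    "zero_invariant_log",
    "PercentScaler",
    "percent_normalize",
    "residual_confound_check",
]


@dataclass(frozen=True)
class OutlierReport:
    """Result of a single-marker Grubbs scan."""

    marker: str
    subject_index: int | None
    statistic_G: float
    p_value: float
    removed: bool


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for sample size ``n`` at ``alpha``.

    G_crit = (n−1)/√n · √(t² / (n − 2 + t²)) with t the upper
    α/(2n) quantile of Student's t with n−2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_scan(values: np.ndarray, alpha: float = 0.05, marker: str = "") -> OutlierReport:
    """Screen one concentration vector for a single extreme value.

    G = max|x_i − mean| / sd (ddof=1). The most deviant point is flagged
    iff G exceeds the two-sided critical value at ``alpha``. At most one
    point is flagged per call; a zero-variance vector yields no outlier.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("Grubbs test requires at least 3 observations")
    if not np.all(np.isfinite(values)):
        raise ValueError("Grubbs test requires finite values")
    sd = values.std(ddof=1)
    if sd == 0:
        warnings.warn(f"zero variance in marker {marker!r}: no outlier test possible")
        return OutlierReport(marker, None, 0.0, 1.0, False)
    deviations = np.abs(values - values.mean())
    idx = int(np.argmax(deviations))
    g = deviations[idx] / sd
    n = values.size
    # p-value by inverting the critical-value relation
    t_sq = (n - 2) * g**2 / ((n - 1) ** 2 / n - g**2) if g**2 < (n - 1) ** 2 / n else np.inf
    p = min(1.0, 2 * n * stats.t.sf(np.sqrt(t_sq), n - 2))
    removed = g > grubbs_critical_value(n, alpha)
    return OutlierReport(marker, idx if removed else None, float(g), float(p), removed)


class ConfoundCorrector(BaseEstimator, TransformerMixin):
    """Per-marker age and sex confound correction for cohort tables.

    fit() estimates, per marker, the correction age slope (negated OLS
    slope of concentration on age), the male − female median difference,
    and the reference age (cohort minimum). transform() applies the
    correction formula exactly.

    Parameters
    ----------
    controls_only : bool
        Fit the correction parameters on the healthy controls only
        (default) instead of the pooled cohort. Pooled fitting absorbs
        part of any disease effect that is correlated with age into the
        slopes and leaves residual age association; controls-only
        fitting estimates the physiological trend.
    """

    def __init__(self, controls_only: bool = True):
        self.controls_only = controls_only

    def fit(self, cohort: pd.DataFrame, y=None) -> "ConfoundCorrector":
        sub = cohort[cohort["diagnosis"] == "healthy"] if self.controls_only else cohort
        if sub["age"].nunique() < 2:
            raise ValueError("age variance must be positive to fit the correction")
        markers = marker_columns(sub)
        age = sub["age"].to_numpy(float)
        male = sub["sex"].to_numpy() == "m"
        single_sex = male.all() or (~male).all()
        if not single_sex and (male.sum() < 3 or (~male).sum() < 3):
            raise ValueError("need at least 3 subjects per sex")
        if single_sex:
            warnings.warn("single-sex cohort: sex correction term set to 0")

        design = np.column_stack([np.ones_like(age), age])
        rows = []
        for m in markers:
            y_m = sub[m].to_numpy(float)
            coef, *_ = np.linalg.lstsq(design, y_m, rcond=None)
            sex_diff = 0.0 if single_sex else float(
                np.median(y_m[male]) - np.median(y_m[~male])
            )
            rows.append((m, -float(coef[1]), sex_diff))
        self.model_ = pd.DataFrame(
            rows, columns=["marker", "age_slope", "sex_median_difference"]
        ).set_index("marker")
        self.reference_age_ = float(sub["age"].min())
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "model_")
        markers = marker_columns(cohort)
        missing = [m for m in markers if m not in self.model_.index]
        if missing:
            raise KeyError(f"correction model is missing marker(s) {missing}")
        out = cohort.copy()
        age_term = cohort["age"].to_numpy(float) - self.reference_age_
        male = cohort["sex"].to_numpy() == "m"
        for m in markers:
            slope = self.model_.at[m, "age_slope"]
            sex_diff = self.model_.at[m, "sex_median_difference"]
            out[m] = (
                cohort[m].to_numpy(float)
                + age_term * slope
                - np.where(male, sex_diff, 0.0)
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        """Serializable model: marker, age_slope, sex_median_difference, reference_age."""
        check_is_fitted(self, "model_")
        out = self.model_.reset_index()
        out["reference_age"] = self.reference_age_
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfoundCorrector":
        obj = cls()
        obj.model_ = frame.set_index("marker")[["age_slope", "sex_median_difference"]]
        obj.reference_age_ = float(frame["reference_age"].iloc[0])
        return obj


def fit_correction(cohort: pd.DataFrame, controls_only: bool = True) -> ConfoundCorrector:
    """Fit a :class:`ConfoundCorrector` on a cohort table."""
    return ConfoundCorrector(controls_only=controls_only).fit(cohort)


def apply_correction(cohort: pd.DataFrame, model: ConfoundCorrector) -> pd.DataFrame:
    """Apply a fitted correction model to a cohort table."""
    return model.transform(cohort)


def safe_log1p(x: np.ndarray, floor: float = -1.0 + 1e-3) -> np.ndarray:
    """ln(x+1) with inputs clipped to the transform's domain.

    Confound correction can push a low concentration slightly below −1
    ng/ml (slope-estimate noise times a large age span); such values are
    clipped to ``floor`` so downstream density fits stay finite. The
    clip count is reported via a warning.
    """
    x = np.asarray(x, dtype=float)
    n_below = int((x < floor).sum())
    if n_below:
        warnings.warn(f"{n_below} corrected value(s) below {floor:.3f} clipped for ln(x+1)")
    return np.log1p(np.maximum(x, floor))


def zero_invariant_log(cohort: pd.DataFrame, clip: bool = False) -> pd.DataFrame:
    """Elementwise ln(x + 1) on all marker columns (0 maps to 0).

    Values ≤ −1 are an error unless ``clip`` is set, in which case they
    are clipped into the transform's domain (see :func:`safe_log1p`).
    """
    out = cohort.copy()
    for m in marker_columns(cohort):
        x = cohort[m].to_numpy(float)
        if np.any(x <= -1):
            if not clip:
                raise ValueError(f"values <= -1 in marker {m!r}: ln(x+1) undefined")
            out[m] = safe_log1p(x)
        else:
            out[m] = np.log1p(x)
    return out


class PercentScaler(BaseEstimator, TransformerMixin):
    """Per-feature min–max scaling to [0, 100].

    Constant features map to 0 with a warning. Preserves within-feature
    ordering; intended to make heterogeneous marker scales compatible
    with the Euclidean distance for projection and kNN.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.range_ = X.max(axis=0) - self.min_
        return self

    def transform(self, X):
        check_is_fitted(self, "min_")
        X = np.asarray(X, dtype=float)
        out = np.zeros_like(X)
        nonconst = self.range_ > 0
        if not nonconst.all():
            warnings.warn(
                f"{int((~nonconst).sum())} constant feature(s) mapped to 0 in percent scaling"
            )
        out[:, nonconst] = 100.0 * (X[:, nonconst] - self.min_[nonconst]) / self.range_[nonconst]
        return out


def percent_normalize(cohort: pd.DataFrame) -> pd.DataFrame:
    """Min–max scale every marker column of a cohort table to [0, 100]."""
    markers = marker_columns(cohort)
    out = cohort.copy()
    out[markers] = PercentScaler().fit_transform(cohort[markers].to_numpy(float))
    return out


def residual_confound_check(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-marker residual association with age and sex.

    Returns a frame indexed by marker with Spearman ρ and p against age,
    and the two-sided rank-sum (Mann–Whitney U) p for the male/female
    comparison.
    """
    markers = marker_columns(cohort)
    age = cohort["age"].to_numpy(float)
    male = cohort["sex"].to_numpy() == "m"
    rows = []
    for m in markers:
        x = cohort[m].to_numpy(float)
        rho, p_age = stats.spearmanr(x, age)
        if male.any() and (~male).any():
            p_sex = float(stats.mannwhitneyu(x[male], x[~male], alternative="two-sided").pvalue)
        else:
            p_sex = np.nan
        rows.append((m, float(rho), float(p_age), p_sex))
    return pd.DataFrame(
        rows, columns=["marker", "age_rho", "age_p", "sex_p"]
    ).set_index("marker")


def scan_outliers(
    cohort: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, list[OutlierReport]]:
    """Grubbs-scan every marker once; null flagged values (at most one per marker).

    Returns the screened cohort (flagged entries set to NaN are dropped
    from that marker by replacement with the marker median, keeping the
    table rectangular) and the per-marker reports.
    """
    out = cohort.copy()
    reports = []
    for m in marker_columns(cohort):
        rep = grubbs_scan(cohort[m].to_numpy(float), alpha=alpha, marker=m)
        reports.append(rep)
        if rep.removed:
            med = float(cohort[m].drop(index=cohort.index[rep.subject_index]).median())
            out.iloc[rep.subject_index, out.columns.get_loc(m)] = med
    return out, reports
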