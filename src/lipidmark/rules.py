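"""The symbolic rule-sum biomarker.

Per marker, the class-conditional density of the zero-invariant
log-transformed concentration is modeled as a Gaussian mixture

    p(x) = Σ_i w_i · N(x | mean_i, sd_i),   Σ_i w_i = 1,

fitted by expectation-maximization with the component count M chosen by
the Bayesian information criterion (M = 1..M_max). The Bayesian
decision threshold of a marker is the crossing point of the two
prior-weighted class densities; the rule's direction follows the class
means (a rule votes for the patient class on the side of the threshold
where the patient mean lies). The classifier counts satisfied rules
into a score SF and predicts the patient class when SF >= t, with t
chosen to maximize sensitivity × specificity over t = 1..|rules|.

Thresholds are derived on the log scale and reported back-transformed
(e^x − 1) to ng/ml on the corrected concentration scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GmmFit",
    "DecisionRule",
    "fit_class_densities",
    "derive_rule",
    "score_subject",
    "optimize_threshold",
    "RuleSumClassifier",
    "classify",
    "save_classifier",
    "load_classifier",
]

_SD_FLOOR = 1e-6


@dataclass(frozen=True)
class GmmFit:
    """A one-dimensional Gaussian mixture for one class of one marker."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    log_likelihood: float
    label: str  # "MS" or "healthy"

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        """Overall mixture mean."""
        return float(np.dot(self.weights, self.means))

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, m, s in zip(self.weights, self.means, self.sds):
            out = out + w * norm.pdf(x, m, s)
        return out


def fit_class_densities(
    values: np.ndarray,
    labels: np.ndarray,
    M_max: int = 3,
    seed: int = 0,
) -> tuple[GmmFit, GmmFit]:
    """Fit one Gaussian mixture per class (patients, then healthy).

    EM fits for M = 1..M_max per class; M selected by BIC. A degenerate
    (zero-variance) class is forced to M = 1 with the SD floored.
    Deterministic for a fixed seed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    fits = []
    for cls, name in ((1, "MS"), (0, "healthy")):
        x = values[labels == cls]
        if x.size < 5:
            raise ValueError(f"need >= 5 observations for class {name!r}")
        fits.append(_fit_gmm_1d(x, M_max=M_max, seed=seed, label=name))
    return fits[0], fits[1]


def _fit_gmm_1d(x: np.ndarray, M_max: int, seed: int, label: str) -> GmmFit:
    x = x.reshape(-1, 1)
    if np.ptp(x) == 0:
        return GmmFit((1.0,), (float(x[0, 0]),), (_SD_FLOOR,), 0.0, label)
    best = None
    best_bic = np.inf
    for m in range(1, M_max + 1):
        gm = GaussianMixture(
            n_components=m,
            covariance_type="diag",
            reg_covar=1e-8,
            n_init=2,
            random_state=seed,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-12:
            best_bic = bic
            best = gm
    sds = np.sqrt(best.covariances_.ravel())
    return GmmFit(
        tuple(best.weights_.tolist()),
        tuple(best.means_.ravel().tolist()),
        tuple(np.maximum(sds, _SD_FLOOR).tolist()),
        float(best.score(x) * x.size),
        label,
    )


@dataclass(frozen=True)
class DecisionRule:
    """Per-marker threshold rule; the rule votes for the patient class
    when the corrected concentration is on the stated side."""

    marker: str
    threshold_ng_ml: float  # corrected raw scale, back-transformed e^x − 1
    direction: str  # "<" or ">": condition under which the rule votes MS

    @property
    def threshold_log(self) -> float:
        """The ln(x+1)-scale twin of the threshold."""
        return float(np.log1p(self.threshold_ng_ml))

    def applies(self, values_ng_ml) -> np.ndarray:
        v = np.asarray(values_ng_ml, dtype=float)
        if self.direction == "<":
            return v < self.threshold_ng_ml
        return v > self.threshold_ng_ml


def derive_rule(
    fit_ms: GmmFit,
    fit_h: GmmFit,
    prior_ms: float,
    prior_h: float,
    data_range: tuple[float, float] | None = None,
    marker: str = "",
) -> DecisionRule:
    """Bayesian crossing threshold between two class densities.

    The threshold is a root of prior_MS·p(x|MS) − prior_H·p(x|healthy),
    found numerically on the observed data range; with multiple
    crossings, the one nearest the midpoint of the two class means is
    used. The direction is ">" iff the patient mean exceeds the healthy
    mean. Without a crossing on the range, the midpoint of the class
    means is used with a warning.
    """
    if prior_ms <= 0 or prior_h <= 0:
        raise ValueError("class priors must be positive")
    mid = 0.5 * (fit_ms.mean + fit_h.mean)
    if data_range is None:
        lo = min(min(fit_ms.means), min(fit_h.means)) - 4 * max(max(fit_ms.sds), max(fit_h.sds))
        hi = max(max(fit_ms.means), max(fit_h.means)) + 4 * max(max(fit_ms.sds), max(fit_h.sds))
    else:
        lo, hi = data_range

    def diff(x):
        return prior_ms * fit_ms.pdf(x) - prior_h * fit_h.pdf(x)

    grid = np.linspace(lo, hi, 2001)
    vals = diff(grid)
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(float(a))
        elif fa * fb < 0:
            roots.append(float(brentq(diff, a, b, xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if roots:
        threshold = min(roots, key=lambda r: abs(r - mid))
    else:
        warnings.warn(
            f"no density crossing on the data range for marker {marker!r}; "
            "using the class-mean midpoint"
        )
        threshold = mid
    direction = ">" if fit_ms.mean > fit_h.mean else "<"
    return DecisionRule(
        marker=marker, threshold_ng_ml=float(np.expm1(threshold)), direction=direction
    )


def score_subject(rules: list[DecisionRule], x) -> int:
    """Rule sum SF for a single subject.

    ``x`` maps marker name → corrected concentration (ng/ml); a missing
    marker is an error naming the marker.
    """
    sf = 0
    for rule in rules:
        if rule.marker not in x:
            raise KeyError(f"missing value for marker {rule.marker!r}")
        sf += int(rule.applies(x[rule.marker]))
    return sf


def optimize_threshold(scores, labels) -> tuple[int, float]:
    """Best rule-sum threshold t* maximizing sensitivity × specificity.

    t ranges over 1..max score count; predicted patient iff SF >= t.
    Ties break toward the smallest t. Returns (t*, best product).
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    pos = labels == 1
    t_max = int(scores.max()) if scores.max() >= 1 else 1
    best_t, best_prod = 1, -1.0
    for t in range(1, t_max + 1):
        pred = scores >= t
        sens = (pred & pos).sum() / pos.sum()
        spec = (~pred & ~pos).sum() / (~pos).sum()
        prod = sens * spec
        if prod > best_prod + 1e-15:
            best_t, best_prod = t, prod
    return best_t, float(best_prod)


class RuleSumClassifier(BaseEstimator, ClassifierMixin):
    """Interpretable rule-sum biomarker over a marker panel.

    fit() consumes a DataFrame of corrected concentrations (one column
    per panel marker) and binary labels (1 = patient). Per marker a
    Gaussian-mixture density is fitted per class on the ln(x+1) scale,
    the Bayesian crossing threshold and direction derived, and the
    rule-sum threshold ``t_`` optimized on the training scores.

    Parameters
    ----------
    M_max : int
        Maximum mixture components per class density (BIC-selected).
    priors : "prevalence" or "equal"
        Class priors weighting the density crossing.
    random_state : int
        Seeds the EM initializations.
    """

    def __init__(self, M_max: int = 3, priors: str = "prevalence", random_state: int = 0):
        self.M_max = M_max
        self.priors = priors
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y) -> "RuleSumClassifier":
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        if self.priors == "prevalence":
            prior_ms = float((y == 1).mean())
            prior_h = 1.0 - prior_ms
        elif self.priors == "equal":
            prior_ms = prior_h = 0.5
        else:
            raise ValueError(f"unknown priors {self.priors!r}")
        from .preprocess import safe_log1p

        rules = []
        self.density_fits_ = {}
        for marker in X.columns:
            logs = safe_log1p(X[marker].to_numpy(float))
            fit_ms, fit_h = fit_class_densities(
                logs, y, M_max=self.M_max, seed=self.random_state
            )
            rule = derive_rule(
                fit_ms,
                fit_h,
                prior_ms,
                prior_h,
                data_range=(float(logs.min()), float(logs.max())),
                marker=str(marker),
            )
            self.density_fits_[str(marker)] = (fit_ms, fit_h)
            rules.append(rule)
        self.rules_ = rules
        scores = self.decision_function(X)
        self.t_, self.train_product_ = optimize_threshold(scores, y)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Rule sum SF per subject (0..|rules|)."""
        check_is_fitted(self, "rules_")
        X = pd.DataFrame(X)
        sf = np.zeros(len(X), dtype=int)
        for rule in self.rules_:
            if rule.marker not in X.columns:
                raise KeyError(f"missing value for marker {rule.marker!r}")
            sf += rule.applies(X[rule.marker].to_numpy(float)).astype(int)
        return sf

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Patient (1) iff SF >= t, else healthy (0)."""
        check_is_fitted(self, "t_")
        return (self.decision_function(X) >= self.t_).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Machine-readable rule table plus the one-line t record."""
        check_is_fitted(self, "rules_")
        rows = [
            {"marker": r.marker, "threshold_ng_ml": r.threshold_ng_ml, "direction": r.direction}
            for r in self.rules_
        ]
        rows.append({"marker": "__t__", "threshold_ng_ml": float(self.t_), "direction": ""})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RuleSumClassifier":
        obj = cls()
        rules = []
        t = None
        for _, row in frame.iterrows():
            if row["marker"] == "__t__":
                t = int(row["threshold_ng_ml"])
            else:
                rules.append(
                    DecisionRule(
                        marker=str(row["marker"]),
                        threshold_ng_ml=float(row["threshold_ng_ml"]),
                        direction=str(row["direction"]),
                    )
                )
        if t is None:
            raise ValueError("serialized classifier lacks the t record")
        obj.rules_ = rules
        obj.t_ = t
        obj.classes_ = np.array([0, 1])
        return obj


def classify(classifier: RuleSumClassifier, X: pd.DataFrame) -> np.ndarray:
    """Functional wrapper: predicted labels (1 = patient)."""
    return classifier.predict(X)


def save_classifier(classifier: RuleSumClassifier, destination) -> None:
    classifier.to_frame().to_csv(destination, index=False, float_format="%.17g")


def load_classifier(source) -> RuleSumClassifier:
    return RuleSumClassifier.from_frame(pd.read_csv(source))
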