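"""Benchmark learners: kNN, adaptive boosting, random forests.

Comparison plumbing around standard scikit-learn implementations, used
to choose the forest as the basis of feature selection and to put the
symbolic rule-sum biomarker's performance in context. All learners
consume zero-invariant log-transformed concentrations; kNN additionally
sees per-feature percent normalization (min–max to [0, 100]) so the
Euclidean metric is not dominated by high-concentration markers.
Printed settings: k = 5, 500 boosting iterations, 1,000 forest trees
with √d candidate features per split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline

from .cohort import diagnosis_vector, marker_columns
from .evaluation import performance_report, stratified_split
from .preprocess import PercentScaler, safe_log1p
from .rules import RuleSumClassifier

__all__ = ["LearnerSpec", "make_estimator", "fit_and_predict", "compare_learners"]


@dataclass(frozen=True)
class LearnerSpec:
    """One benchmark learner configuration."""

    kind: str  # "knn" | "boosting" | "forest"
    feature_set: str = "full"  # "full" | "reduced"
    k: int = 5
    iterations: int = 500
    n_trees: int = 1000

    def label(self) -> str:
        names = {
            "knn": "k-nearest neighbors",
            "boosting": "adaptive boosting",
            "forest": "random forests",
        }
        return f"{names[self.kind]}, {self.feature_set} feature set"


def make_estimator(spec: LearnerSpec, seed: int = 0):
    """Instantiate the scikit-learn estimator for a LearnerSpec."""
    if spec.kind == "knn":
        return Pipeline(
            [("percent", PercentScaler()), ("knn", KNeighborsClassifier(n_neighbors=spec.k))]
        )
    if spec.kind == "boosting":
        return AdaBoostClassifier(n_estimators=spec.iterations, random_state=seed)
    if spec.kind == "forest":
        return RandomForestClassifier(
            n_estimators=spec.n_trees, max_features="sqrt", random_state=seed
        )
    raise ValueError(f"unknown learner kind {spec.kind!r}")


def _design(cohort: pd.DataFrame, panel: list[str] | None) -> np.ndarray:
    cols = panel if panel is not None else marker_columns(cohort)
    return safe_log1p(cohort[cols].to_numpy(float))


def fit_and_predict(
    spec: LearnerSpec,
    train: pd.DataFrame,
    test: pd.DataFrame,
    panel: list[str] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one learner and predict the test cohort.

    Returns (predicted labels, positive-class scores). The reduced
    feature set uses ``panel``; the full set uses every marker column.
    """
    cols = panel if spec.feature_set == "reduced" else None
    if spec.feature_set == "reduced" and panel is None:
        raise ValueError("reduced feature set requires a marker panel")
    X_train, X_test = _design(train, cols), _design(test, cols)
    y_train = diagnosis_vector(train)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training cohort must contain both classes")
    est = make_estimator(spec, seed=seed)
    est.fit(X_train, y_train)
    predicted = est.predict(X_test)
    scores = est.predict_proba(X_test)[:, 1]
    return predicted.astype(int), scores


def compare_learners(
    cohort: pd.DataFrame,
    panel: list[str],
    seed: int = 0,
    train_fraction: float = 2 / 3,
    n_bootstrap: int = 1000,
    M_max: int = 3,
) -> pd.DataFrame:
    """Head-to-head comparison on one shared stratified split.

    Evaluates kNN, boosting and the forest on the full marker set, the
    forest on the reduced ``panel``, and the symbolic rule-sum
    classifier on the same test subjects; every learner's predictions
    go through the single shared evaluation path. Returns a metrics ×
    learners table (point estimates with bootstrap CI columns).
    """
    train, test = stratified_split(cohort, train_fraction=train_fraction, seed=seed)
    y_test = diagnosis_vector(test)
    specs = [
        LearnerSpec("knn"),
        LearnerSpec("boosting"),
        LearnerSpec("forest", "full"),
        LearnerSpec("forest", "reduced"),
    ]
    columns: dict[str, pd.DataFrame] = {}
    for i, spec in enumerate(specs):
        predicted, scores = fit_and_predict(spec, train, test, panel=panel, seed=seed + i)
        rep = performance_report(
            y_test, predicted, scores, n_bootstrap=n_bootstrap, seed=seed
        )
        columns[spec.label()] = rep.to_frame().set_index("metric")

    symbolic = RuleSumClassifier(M_max=M_max, random_state=seed)
    symbolic.fit(train[panel], diagnosis_vector(train))
    pred = symbolic.predict(test[panel])
    sf = symbolic.decision_function(test[panel]).astype(float)
    rep = performance_report(y_test, pred, sf, n_bootstrap=n_bootstrap, seed=seed)
    columns["symbolic classifier"] = rep.to_frame().set_index("metric")

    out = {}
    for name, frame in columns.items():
        out[(name, "point")] = frame["point"]
        out[(name, "ci_low")] = frame["ci_low"]
        out[(name, "ci_high")] = frame["ci_high"]
    return pd.DataFrame(out)
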