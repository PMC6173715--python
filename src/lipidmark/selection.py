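"""Feature selection: repeated random-forest importance + computed ABC.

The marker panel is distilled in nested resampling runs. Per run, an
inner train/validation split is drawn from the training cohort, a
bagged forest of decision trees is grown on an equal-group subsample of
the inner training data, and each marker's importance is measured as
the out-of-bag mean decrease in classification accuracy when the
marker's values are permuted. Computed ABC analysis then categorizes
the importances into a most-profitable set A, an intermediate set B and
a trivial set C; the sizes and memberships of set A over all runs
determine the final panel (modal size, frequency-ordered membership).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.tree import DecisionTreeClassifier

from .cohort import diagnosis_vector, marker_columns
from .preprocess import zero_invariant_log

__all__ = [
    "ImportanceVector",
    "AbcResult",
    "SelectionSummary",
    "rf_importance_run",
    "abc_analysis",
    "repeat_selection",
    "finalize_panel",
    "expert_veto",
    "RepeatedPanelSelector",
]


@dataclass
class ImportanceVector:
    """Per-marker importance from one forest run."""

    importances: pd.Series  # mean decrease in OOB accuracy per marker
    out_of_bag_error: float
    run_id: int = 0


@dataclass
class AbcResult:
    """Computed ABC categorization of non-negative contributions.

    The cumulative contribution curve lives in the unit square, from
    (0, 0) to (1, 1). Set A ends at the curve point nearest the ideal
    point (0, 1) (Pareto point); set B extends to the break-even point
    where the curve's slope first falls to <= 1 (contribution <= mean);
    set C is the positive remainder. Zero-contribution items belong to
    no set.
    """

    items: list  # decreasing contribution order
    contributions: np.ndarray  # sorted decreasing
    curve_x: np.ndarray
    curve_y: np.ndarray
    set_a: list
    set_b: list
    set_c: list


def rf_importance_run(
    train: pd.DataFrame,
    n_trees: int = 500,
    max_features: int = 6,
    seed: int = 0,
    run_id: int = 0,
) -> ImportanceVector:
    """One equal-group forest run with OOB permutation importance.

    An equal-group subsample (minority-class size per class) is drawn
    from ``train``; ``n_trees`` decision trees, each considering up to
    ``max_features`` randomly drawn features per split, are fitted on
    bootstrap resamples of the subsample (ln(x+1)-transformed
    concentrations). Importance of a marker is the mean over trees of
    the decrease in out-of-bag accuracy when the marker's OOB values are
    permuted; the aggregate OOB majority-vote error is recorded.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    y_all = diagnosis_vector(train)
    if min((y_all == 1).sum(), (y_all == 0).sum()) < 2:
        raise ValueError("each class needs at least 2 subjects")
    markers = marker_columns(train)
    X_all = zero_invariant_log(train, clip=True)[markers].to_numpy(float)

    rng = np.random.default_rng(seed)
    # equal group sizes: minority-class count drawn from each class
    idx_pos = np.flatnonzero(y_all == 1)
    idx_neg = np.flatnonzero(y_all == 0)
    m = min(len(idx_pos), len(idx_neg))
    keep = np.concatenate(
        [rng.choice(idx_pos, m, replace=False), rng.choice(idx_neg, m, replace=False)]
    )
    X, y = X_all[keep], y_all[keep]
    n, d = X.shape
    mtry = min(max_features, d)

    importance_sum = np.zeros(d)
    vote_sum = np.zeros(n)
    vote_cnt = np.zeros(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features=mtry, random_state=int(rng.integers(2**31))
        ).fit(X[boot], y[boot])
        if len(oob) == 0:
            continue
        base_pred = tree.predict(X[oob])
        vote_sum[oob] += base_pred
        vote_cnt[oob] += 1
        base_correct = (base_pred == y[oob]).sum()
        used = np.unique(tree.tree_.feature[tree.tree_.feature >= 0])
        for f in used:
            Xp = X[oob].copy()
            Xp[:, f] = Xp[rng.permutation(len(oob)), f]
            perm_correct = (tree.predict(Xp) == y[oob]).sum()
            importance_sum[f] += (base_correct - perm_correct) / len(oob)

    seen = vote_cnt > 0
    oob_error = float(np.mean((vote_sum[seen] / vote_cnt[seen] >= 0.5).astype(int) != y[seen]))
    return ImportanceVector(
        importances=pd.Series(importance_sum / n_trees, index=markers),
        out_of_bag_error=oob_error,
        run_id=run_id,
    )


def abc_analysis(contributions, items=None) -> AbcResult:
    """Computed ABC analysis of non-negative per-item contributions.

    Items are sorted by decreasing contribution; the cumulative fraction
    curve is evaluated at every item. Negative inputs are clipped to 0
    with a warning; an all-zero input is an error.
    """
    values = np.asarray(contributions, dtype=float)
    if values.size < 3:
        raise ValueError("ABC analysis requires at least 3 items")
    if items is None:
        items = list(range(values.size))
    items = list(items)
    if np.any(values < 0):
        warnings.warn("negative contributions clipped to 0 for ABC analysis")
        values = np.clip(values, 0, None)
    total = values.sum()
    if total == 0:
        raise ValueError("all contributions are zero")

    order = np.argsort(-values, kind="stable")
    sorted_vals = values[order]
    sorted_items = [items[i] for i in order]
    n = values.size
    curve_x = np.arange(1, n + 1) / n
    curve_y = np.cumsum(sorted_vals) / total

    dist_sq = curve_x**2 + (1.0 - curve_y) ** 2
    k_a = int(np.argmin(dist_sq))  # inclusive index of last set-A item
    # break-even: first item whose segment slope dy/dx <= 1, i.e. contribution <= mean
    slopes = sorted_vals * n / total
    below = np.flatnonzero(slopes <= 1.0)
    k_be = int(below[0]) if below.size else n  # first index in set C
    k_be = max(k_be, k_a + 1)

    positive = sorted_vals > 0
    set_a = [it for i, it in enumerate(sorted_items) if i <= k_a and positive[i]]
    set_b = [it for i, it in enumerate(sorted_items) if k_a < i < k_be and positive[i]]
    set_c = [it for i, it in enumerate(sorted_items) if i >= k_be and positive[i]]
    return AbcResult(sorted_items, sorted_vals, curve_x, curve_y, set_a, set_b, set_c)


@dataclass
class SelectionSummary:
    """Aggregate of set-A sizes and memberships over resampling runs."""

    size_histogram: dict[int, int]
    membership_counts: pd.Series  # per marker: runs with membership in set A
    mean_importance: pd.Series
    n_runs: int
    oob_errors: list[float] = field(default_factory=list)

    @property
    def final_size(self) -> int:
        """Modal set-A size; ties broken toward the smaller size."""
        best = max(self.size_histogram.items(), key=lambda kv: (kv[1], -kv[0]))
        return best[0]


def repeat_selection(
    train: pd.DataFrame,
    n_runs: int = 1000,
    n_trees: int = 500,
    max_features: int = 6,
    seed: int = 0,
    inner_fraction: float = 2 / 3,
) -> SelectionSummary:
    """Nested-resampling feature selection.

    Per run an inner train split (stratified, ``inner_fraction``) is
    drawn from ``train``; a forest importance run followed by ABC
    analysis records the size and members of set A. Deterministic for a
    fixed master ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    y = diagnosis_vector(train)
    markers = marker_columns(train)
    counts = pd.Series(0, index=markers, dtype=int)
    importance_acc = pd.Series(0.0, index=markers)
    hist: dict[int, int] = {}
    oob_errors = []
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    for run in range(n_runs):
        inner = []
        for idx in (idx_pos, idx_neg):
            take = int(np.floor(inner_fraction * len(idx) + 0.5))
            inner.append(rng.choice(idx, take, replace=False))
        inner_df = train.iloc[np.concatenate(inner)]
        iv = rf_importance_run(
            inner_df,
            n_trees=n_trees,
            max_features=max_features,
            seed=int(rng.integers(2**31)),
            run_id=run,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # negative importances are expected noise
            abc = abc_analysis(iv.importances.to_numpy(), items=markers)
        hist[len(abc.set_a)] = hist.get(len(abc.set_a), 0) + 1
        counts[abc.set_a] += 1
        importance_acc += iv.importances
        oob_errors.append(iv.out_of_bag_error)
    return SelectionSummary(
        size_histogram=hist,
        membership_counts=counts,
        mean_importance=importance_acc / n_runs,
        n_runs=n_runs,
        oob_errors=oob_errors,
    )


def finalize_panel(summary: SelectionSummary) -> list[str]:
    """Final marker panel: the modal set-A size' top markers by set-A
    membership frequency (ties: larger mean importance, then name)."""
    if summary.n_runs < 1 or not summary.size_histogram:
        raise ValueError("empty selection summary")
    ranking = _ranking(summary)
    return ranking[: summary.final_size]


def _ranking(summary: SelectionSummary) -> list[str]:
    frame = pd.DataFrame(
        {
            "marker": summary.membership_counts.index,
            "count": summary.membership_counts.to_numpy(),
            "importance": summary.mean_importance.reindex(
                summary.membership_counts.index
            ).to_numpy(),
        }
    ).sort_values(
        by=["count", "importance", "marker"],
        ascending=[False, False, True],
        kind="stable",
    )
    return list(frame["marker"])


def expert_veto(panel: list[str], exclusion_list, summary: SelectionSummary | None = None) -> list[str]:
    """Remove vetoed markers, preserving panel size where replacements exist.

    Markers named in ``exclusion_list`` are removed; when a
    ``SelectionSummary`` is supplied, the next-ranked non-vetoed markers
    are promoted to preserve the panel size. Veto of an absent marker is
    a logged no-op.
    """
    exclusion = set(exclusion_list)
    absent = exclusion - set(panel)
    for name in sorted(absent):
        warnings.warn(f"veto of {name!r}: marker not in panel, no-op")
    kept = [m for m in panel if m not in exclusion]
    if summary is not None and len(kept) < len(panel):
        for candidate in _ranking(summary):
            if len(kept) == len(panel):
                break
            if candidate not in kept and candidate not in exclusion:
                warnings.warn(f"veto replacement: {candidate!r} promoted into panel")
                kept.append(candidate)
    return kept


class RepeatedPanelSelector(BaseEstimator):
    """Estimator facade over the nested-resampling panel selection.

    fit() consumes a cohort table (metadata + concentration columns) and
    exposes ``summary_``, ``ranking_`` and ``panel_``.
    """

    def __init__(
        self,
        n_runs: int = 1000,
        n_trees: int = 500,
        max_features: int = 6,
        inner_fraction: float = 2 / 3,
        exclusion_list: tuple = (),
        random_state: int = 0,
    ):
        self.n_runs = n_runs
        self.n_trees = n_trees
        self.max_features = max_features
        self.inner_fraction = inner_fraction
        self.exclusion_list = exclusion_list
        self.random_state = random_state

    def fit(self, cohort: pd.DataFrame, y=None) -> "RepeatedPanelSelector":
        self.summary_ = repeat_selection(
            cohort,
            n_runs=self.n_runs,
            n_trees=self.n_trees,
            max_features=self.max_features,
            seed=self.random_state,
            inner_fraction=self.inner_fraction,
        )
        self.ranking_ = _ranking(self.summary_)
        panel = finalize_panel(self.summary_)
        self.panel_ = expert_veto(panel, self.exclusion_list, self.summary_)
        return self

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "panel_")
        meta = [c for c in cohort.columns if c not in marker_columns(cohort)]
        return cohort[meta + self.panel_]
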