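"""Gaussian-mixture densities, Bayesian thresholds, rule-sum classifier."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from lipidmark.rules import (
    DecisionRule,
    GmmFit,
    RuleSumClassifier,
    derive_rule,
    fit_class_densities,
    load_classifier,
    optimize_threshold,
    save_classifier,
    score_subject,
)


def _fit_pair(rng, mu_ms=0.0, mu_h=2.0, sd=1.0, n=500, M_max=3):
    values = np.concatenate([rng.normal(mu_ms, sd, n), rng.normal(mu_h, sd, n)])
    labels = np.array([1] * n + [0] * n)
    return fit_class_densities(values, labels, M_max=M_max, seed=0)


class TestDensities:
    def test_single_gaussian_selects_one_component(self, rng):
        fit_ms, fit_h = _fit_pair(rng)
        assert fit_ms.n_components == 1
        se = 1.0 / np.sqrt(500)
        assert abs(fit_ms.mean - 0.0) < 3 * se
        assert abs(fit_h.mean - 2.0) < 3 * se

    def test_two_component_mixture_recovered(self, rng):
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(4, 1, 500)])
        labels = np.ones(1000, dtype=int)
        values = np.concatenate([x, rng.normal(0, 1, 10)])
        labels = np.concatenate([labels, np.zeros(10, dtype=int)])
        fit_ms, _ = fit_class_densities(values, labels, M_max=3, seed=0)
        assert fit_ms.n_components == 2
        means = sorted(fit_ms.means)
        assert abs(means[0] - 0.0) < 0.2 and abs(means[1] - 4.0) < 0.2

    @pytest.mark.parametrize("M_max", [1, 2, 3])
    def test_density_integrates_to_one(self, rng, M_max):
        fit_ms, fit_h = _fit_pair(rng, M_max=M_max)
        for fit in (fit_ms, fit_h):
            total, _ = quad(lambda x: fit.pdf(np.array([x]))[0], -30, 30, limit=200)
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_class_floored(self):
        values = np.concatenate([np.full(10, 3.0), np.random.default_rng(0).normal(0, 1, 10)])
        labels = np.array([1] * 10 + [0] * 10)
        fit_ms, _ = fit_class_densities(values, labels)
        assert fit_ms.n_components == 1 and fit_ms.sds[0] > 0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            fit_class_densities(np.arange(6.0), np.array([1, 1, 1, 0, 0, 0]))


def _single(mu, sd):
    return GmmFit((1.0,), (mu,), (sd,), 0.0, "x")


class TestDeriveRule:
    def test_symmetric_crossing_is_midpoint(self):
        rule = derive_rule(_single(0.0, 1.0), _single(2.0, 1.0), 0.5, 0.5)
        assert rule.threshold_log == pytest.approx(1.0, abs=1e-9)
        assert rule.direction == "<"

    def test_unequal_variance_matches_quadratic_oracle(self):
        # crossing of w1·N(0,1) and w2·N(3,2): roots of a quadratic
        s1, s2, m1, m2, w1, w2 = 1.0, 2.0, 0.0, 3.0, 0.5, 0.5
        a = 1 / (2 * s1**2) - 1 / (2 * s2**2)
        b = m2 / s2**2 - m1 / s1**2
        c = m1**2 / (2 * s1**2) - m2**2 / (2 * s2**2) + np.log(
            (w2 * s1) / (w1 * s2)
        )
        roots = np.roots([a, b, c])
        mid = (m1 + m2) / 2
        expected = roots[np.argmin(np.abs(roots - mid))]
        rule = derive_rule(
            _single(m1, s1), _single(m2, s2), w1, w2, data_range=(-6.0, 9.0)
        )
        assert rule.threshold_log == pytest.approx(float(expected), abs=1e-6)

    def test_direction_follows_class_means(self):
        rule = derive_rule(_single(5.0, 1.0), _single(2.0, 1.0), 0.5, 0.5)
        assert rule.direction == ">"
        # applies() consumes raw (ng/ml) values; the fits are log-scale
        assert rule.applies(np.array([np.expm1(5.0)]))[0]
        assert not rule.applies(np.array([np.expm1(2.0)]))[0]

    def test_no_crossing_falls_back_to_midpoint_with_warning(self):
        # disjoint range that excludes the crossing
        with pytest.warns(UserWarning, match="midpoint"):
            rule = derive_rule(
                _single(0.0, 1.0), _single(2.0, 1.0), 0.5, 0.5, data_range=(4.0, 5.0)
            )
        assert rule.threshold_log == pytest.approx(1.0)

    def test_nonpositive_priors_rejected(self):
        with pytest.raises(ValueError):
            derive_rule(_single(0, 1), _single(1, 1), 0.0, 1.0)


class TestScoring:
    def _rules(self):
        return [
            DecisionRule("a", 10.0, "<"),
            DecisionRule("b", 5.0, ">"),
            DecisionRule("c", 2.0, "<"),
        ]

    def test_manual_enumeration(self):
        rules = self._rules()
        assert score_subject(rules, {"a": 20.0, "b": 1.0, "c": 5.0}) == 0
        assert score_subject(rules, {"a": 5.0, "b": 9.0, "c": 1.0}) == 3
        assert score_subject(rules, {"a": 5.0, "b": 1.0, "c": 5.0}) == 1

    def test_missing_marker_named(self):
        with pytest.raises(KeyError, match="'b'"):
            score_subject(self._rules(), {"a": 1.0, "c": 1.0})

    def test_optimize_threshold_matches_exhaustive_search(self, rng):
        for _ in range(50):
            scores = rng.integers(0, 9, 60)
            labels = rng.integers(0, 2, 60)
            if labels.min() == labels.max():
                continue
            t_star, prod = optimize_threshold(scores, labels)
            best = max(
                range(1, scores.max() + 1),
                key=lambda t: (
                    ((scores >= t) & (labels == 1)).sum() / (labels == 1).sum()
                    * (((scores < t) & (labels == 0)).sum() / (labels == 0).sum()),
                    -t,
                ),
            )
            assert t_star == best

    def test_separated_scores_take_smallest_gap_threshold(self):
        scores = np.array([0, 1, 1, 5, 6, 7])
        labels = np.array([0, 0, 0, 1, 1, 1])
        t_star, prod = optimize_threshold(scores, labels)
        assert t_star == 2 and prod == 1.0


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(5)
    n = 150
    X = pd.DataFrame(
        {
            "a": np.expm1(np.concatenate([rng.normal(2, 0.5, n), rng.normal(4, 0.5, n)])),
            "b": np.expm1(np.concatenate([rng.normal(5, 0.5, n), rng.normal(3.5, 0.5, n)])),
        }
    )
    y = np.array([1] * n + [0] * n)
    clf = RuleSumClassifier(random_state=0).fit(X, y)
    return clf, X, y


class TestClassifier:
    def test_boundary_at_t(self, fitted):
        clf, X, y = fitted
        sf = clf.decision_function(X)
        pred = clf.predict(X)
        assert np.array_equal(pred, (sf >= clf.t_).astype(int))

    def test_never_satisfied_rule_changes_nothing(self, fitted):
        clf, X, y = fitted
        pred = clf.predict(X)
        clf2 = RuleSumClassifier.from_frame(clf.to_frame())
        clf2.rules_ = clf2.rules_ + [DecisionRule("a", -1.0, "<")]
        assert np.array_equal(clf2.predict(X), pred)

    def test_raising_t_trades_sensitivity_for_specificity(self, fitted):
        clf, X, y = fitted
        sf = clf.decision_function(X)
        sens, spec = [], []
        for t in range(1, len(clf.rules_) + 1):
            pred = sf >= t
            sens.append((pred & (y == 1)).sum() / (y == 1).sum())
            spec.append((~pred & (y == 0)).sum() / (y == 0).sum())
        assert np.all(np.diff(sens) <= 1e-12)
        assert np.all(np.diff(spec) >= -1e-12)

    def test_serialization_round_trip_exact(self, fitted):
        clf, X, _ = fitted
        buf = io.StringIO()
        save_classifier(clf, buf)
        text = buf.getvalue()
        back = load_classifier(io.StringIO(text))
        assert back.t_ == clf.t_
        for r1, r2 in zip(clf.rules_, back.rules_):
            assert r1 == r2
        buf2 = io.StringIO()
        save_classifier(back, buf2)
        assert buf2.getvalue() == text
        assert np.array_equal(back.predict(X), clf.predict(X))

    def test_refit_is_deterministic(self, fitted):
        clf, X, y = fitted
        clf2 = RuleSumClassifier(random_state=0).fit(X, y)
        assert clf2.t_ == clf.t_
        assert clf2.rules_ == clf.rules_

    def test_planted_directions_recovered(self, corrected, split):
        from conftest import INFORMATIVE

        from lipidmark.cohort import diagnosis_vector

        train, _ = split
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = RuleSumClassifier(random_state=7).fit(
                train[list(INFORMATIVE)], diagnosis_vector(train)
            )
        agree = sum(
            rule.direction == INFORMATIVE[rule.marker] for rule in clf.rules_
        )
        assert agree >= 7
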