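"""Outlier scan, confound correction, transforms: oracles and recovery."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lipidmark.cohort import CohortConfig, MarkerSpec, diagnosis_vector, generate_cohort
from lipidmark.preprocess import (
    ConfoundCorrector,
    PercentScaler,
    apply_correction,
    fit_correction,
    grubbs_critical_value,
    grubbs_scan,
    percent_normalize,
    residual_confound_check,
    zero_invariant_log,
)


def _grubbs_oracle(values, alpha):
    """Direct-formula Grubbs statistic and critical value."""
    values = np.asarray(values, float)
    n = len(values)
    g = np.max(np.abs(values - values.mean())) / values.std(ddof=1)
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
    return g, crit


class TestGrubbs:
    def test_constant_vector_no_outlier(self):
        with pytest.warns(UserWarning, match="zero variance"):
            rep = grubbs_scan(np.array([5.0, 5, 5, 5]))
        assert not rep.removed and rep.statistic_G == 0.0

    def test_known_outlier_flagged_with_oracle_values(self):
        values = np.array([1.0, 2, 3, 4, 100])
        rep = grubbs_scan(values, alpha=0.05)
        g, crit = _grubbs_oracle(values, 0.05)
        assert rep.removed and rep.subject_index == 4
        assert rep.statistic_G == pytest.approx(g, abs=1e-12)
        assert g == pytest.approx(1.789, abs=2e-3)
        assert crit == pytest.approx(1.715, abs=2e-3)

    def test_agrees_with_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            values = rng.normal(0, 1, n)
            if values.std(ddof=1) == 0:
                continue
            rep = grubbs_scan(values)
            g, crit = _grubbs_oracle(values, 0.05)
            assert rep.statistic_G == pytest.approx(g, abs=1e-9)
            assert rep.removed == (g > crit)

    def test_too_few_points_error(self):
        with pytest.raises(ValueError):
            grubbs_scan(np.array([1.0, 2.0]))


def _toy_cohort(n=120, seed=3, age_slope=0.0, sex_offset=0.0):
    spec = MarkerSpec(
        "m1", "ceramide", 3.0, 0.4, age_slope=age_slope, sex_offset=sex_offset
    )
    return generate_cohort(
        CohortConfig(n_patients=n // 2, n_controls=n // 2, markers=(spec,), seed=seed)
    )


class TestCorrection:
    def test_printed_formula_direct_arithmetic(self):
        # value 100 ng/ml, age 28, male, slope 1.6263, sex diff −10.2439,
        # reference age 18 → 100 + 10·1.6263 + 10.2439 = 126.5069
        model = ConfoundCorrector()
        model.model_ = pd.DataFrame(
            {"age_slope": [1.6263], "sex_median_difference": [-10.2439]},
            index=pd.Index(["m1"], name="marker"),
        )
        model.reference_age_ = 18.0
        cohort = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "diagnosis": ["MS", "MS"],
                "age": [28.0, 28.0],
                "sex": ["m", "f"],
                "m1": [100.0, 100.0],
            }
        )
        out = model.transform(cohort)
        assert out.loc[0, "m1"] == pytest.approx(126.5069, abs=1e-10)
        # female: only the age term applies
        assert out.loc[1, "m1"] == pytest.approx(100 + 10 * 1.6263, abs=1e-10)

    def test_zero_model_is_identity(self):
        cohort = _toy_cohort()
        model = ConfoundCorrector()
        model.model_ = pd.DataFrame(
            {"age_slope": [0.0], "sex_median_difference": [0.0]},
            index=pd.Index(["m1"], name="marker"),
        )
        model.reference_age_ = float(cohort["age"].min())
        out = model.transform(cohort)
        np.testing.assert_allclose(out["m1"], cohort["m1"])

    def test_planted_slope_recovered(self):
        cohort = _toy_cohort(n=400, seed=9, age_slope=1.5)
        model = fit_correction(cohort, controls_only=False)
        controls = cohort
        age = controls["age"].to_numpy()
        resid_sd = controls["m1"].to_numpy().std()
        se = resid_sd / (np.sqrt(len(age)) * age.std())
        # stored slope is the correction (negated data) slope
        assert abs(-model.model_.at["m1", "age_slope"] - 1.5) < 3 * se

    def test_refit_on_corrected_cohort_is_null(self):
        cohort = _toy_cohort(n=400, seed=11, age_slope=2.0, sex_offset=5.0)
        model = fit_correction(cohort, controls_only=False)
        corrected = apply_correction(cohort, model)
        refit = fit_correction(corrected, controls_only=False)
        # the sequential age+sex correction is not a joint fit, so the
        # refit slope is only statistically zero (small vs the planted 2.0)
        assert abs(refit.model_.at["m1", "age_slope"]) < 0.02
        assert abs(refit.model_.at["m1", "sex_median_difference"]) < 1.0

    def test_missing_marker_in_model_errors(self):
        cohort = _toy_cohort()
        model = fit_correction(cohort)
        cohort["extra"] = 1.0
        with pytest.raises(KeyError, match="extra"):
            model.transform(cohort)

    def test_single_sex_cohort_warns_and_zeroes_sex_term(self):
        cohort = _toy_cohort(n=200, seed=2)
        cohort["sex"] = "f"
        with pytest.warns(UserWarning, match="single-sex"):
            model = fit_correction(cohort, controls_only=False)
        assert model.model_.at["m1", "sex_median_difference"] == 0.0


class TestTransforms:
    def test_zero_invariant_log_closed_forms(self):
        cohort = pd.DataFrame(
            {
                "subject_id": list("abc"),
                "diagnosis": ["MS", "healthy", "healthy"],
                "age": [30.0, 40.0, 50.0],
                "sex": ["m", "f", "m"],
                "m1": [0.0, np.e - 1, 9.0],
            }
        )
        out = zero_invariant_log(cohort)
        np.testing.assert_allclose(out["m1"], [0.0, 1.0, np.log(10)], atol=1e-12)

    def test_zero_invariant_log_rejects_below_domain(self):
        cohort = _toy_cohort()
        cohort.loc[0, "m1"] = -1.5
        with pytest.raises(ValueError, match="m1"):
            zero_invariant_log(cohort)

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_log_is_strictly_monotone(self, values):
        x = np.sort(np.asarray(values))
        assert np.all(np.diff(np.log1p(x)) > 0)

    def test_percent_normalize_minmax_arithmetic(self):
        X = np.array([[2.0], [4.0], [6.0]])
        out = PercentScaler().fit_transform(X)
        np.testing.assert_allclose(out.ravel(), [0.0, 50.0, 100.0])

    def test_percent_normalize_constant_feature_warns_to_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 4.0]])
        with pytest.warns(UserWarning, match="constant"):
            out = PercentScaler().fit_transform(X)
        np.testing.assert_allclose(out[:, 0], 0.0)
        np.testing.assert_allclose(out[:, 1], [0.0, 100.0])

    def test_percent_normalize_preserves_order(self, rng):
        X = rng.lognormal(1, 1, size=(50, 4))
        out = PercentScaler().fit_transform(X)
        for j in range(4):
            assert np.array_equal(np.argsort(X[:, j]), np.argsort(out[:, j]))


class TestResidualConfounds:
    def test_correction_shrinks_age_correlations(self, cohort, corrected):
        pre = residual_confound_check(cohort)
        post = residual_confound_check(corrected)
        informative = [
            "GluCerC16",
            "HETE15S",
            "LPA20:4",
            "biopterin",
            "OEA",
            "LacCerC24:1",
            "PEA",
            "C16Sphinganin",
        ]
        # strongly confounded markers shrink individually; weakly
        # confounded ones only in aggregate (sampling jitter dominates)
        for m in informative:
            if abs(pre.loc[m, "age_rho"]) > 0.2:
                assert abs(post.loc[m, "age_rho"]) < abs(pre.loc[m, "age_rho"]), m
        assert (
            post.loc[informative, "age_rho"].abs().mean()
            < pre.loc[informative, "age_rho"].abs().mean()
        )

    def test_age_determined_marker_has_unit_rho(self):
        cohort = _toy_cohort(n=100, seed=4)
        cohort["m1"] = cohort["age"] * 2.0
        res = residual_confound_check(cohort)
        assert res.loc["m1", "age_rho"] == pytest.approx(1.0)

    def test_null_cohort_calibration(self):
        # no planted confounds: ~5% of markers significant at alpha=0.05
        markers = tuple(
            MarkerSpec(f"m{i}", "ceramide", 3.0, 0.5) for i in range(30)
        )
        hits, total = 0, 0
        for seed in range(4):
            cohort = generate_cohort(
                CohortConfig(n_patients=50, n_controls=50, markers=markers, seed=seed)
            )
            res = residual_confound_check(cohort)
            hits += (res["age_p"] < 0.05).sum()
            total += len(res)
        assert hits / total < 0.12
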