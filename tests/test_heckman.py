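import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thacea.heckman import (CovariateSpec, EstimationError, LayoutError,
                            expected_productivity, fit_heckman,
                            fit_heckman_imputed, inverse_mills,
                            pool_imputations, predict_earnings,
                            predict_employment_prob)
from thacea.synthetic_data import FUNC_ITEMS, GroundTruth, generate_survey


class TestInverseMills:
    def test_closed_form_at_zero(self):
        assert inverse_mills(0.0) == pytest.approx(np.sqrt(2 / np.pi), abs=1e-5)

    def test_value_at_one(self):
        assert inverse_mills(1.0) == pytest.approx(0.28760, abs=1e-5)

    def test_right_tail_small_and_finite(self):
        v = inverse_mills(8.0)
        assert 0 < v < 1e-3

    def test_stable_deep_in_left_tail(self):
        v = inverse_mills(-40.0)
        assert np.isfinite(v)
        # lambda(z) ~ -z for z -> -inf
        assert v == pytest.approx(40.0, rel=0.01)

    @given(st.floats(-30, 30), st.floats(0.01, 5))
    @settings(max_examples=50, deadline=None)
    def test_positive_and_decreasing(self, z, dz):
        assert inverse_mills(z) > 0
        assert inverse_mills(z + dz) < inverse_mills(z)


class TestFitHeckman:
    def test_stage2_equals_normal_equations_on_tiny_sample(self, truth):
        records, _ = generate_survey(60, truth, m_imputations=1, seed=21)
        # keep enough employed records to identify the earnings equation
        spec = CovariateSpec(
            employment=["age", "female", "func1", "other_income_flag",
                        "other_worker_in_household"],
            earnings=["age", "female", "func1"],
        )
        fit = fit_heckman(records, spec)
        X = np.column_stack([np.ones(len(records)),
                             records[spec.employment].to_numpy(float)])
        imr = inverse_mills(X @ fit.probit_coefficients.to_numpy())
        emp = records["employed"] == 1
        Z = np.column_stack([np.ones(emp.sum()),
                             records.loc[emp, spec.earnings].to_numpy(float),
                             imr[emp.to_numpy()]])
        y = np.log(records.loc[emp, "earnings"].to_numpy(float))
        beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
        np.testing.assert_allclose(fit.earnings_coefficients.to_numpy(), beta,
                                   atol=1e-8)

    def test_no_selection_gives_insignificant_mills_term(self):
        t = GroundTruth(rho=0.0, missing_earnings_fraction=0.0)
        records, _ = generate_survey(5000, t, m_imputations=1, seed=22)
        fit = fit_heckman(records)
        tstat = (fit.earnings_coefficients["imr"]
                 / np.sqrt(fit.earnings_cov.loc["imr", "imr"]))
        assert abs(tstat) < 2

    def test_selection_bias_in_naive_ols_removed_by_correction(self, truth):
        records, _ = generate_survey(5000, truth, m_imputations=1, seed=23)
        fit = fit_heckman(records)
        emp = records["employed"] == 1
        cols = fit.spec.earnings
        Z = np.column_stack([np.ones(emp.sum()), records.loc[emp, cols].to_numpy(float)])
        y = np.log(records.loc[emp, "earnings"].to_numpy(float))
        naive = np.linalg.lstsq(Z, y, rcond=None)[0]
        names = ["const"] + cols
        truth_vec = np.array([truth.earnings_coefs[c] for c in FUNC_ITEMS])
        naive_err = np.abs(np.array([naive[names.index(c)] for c in FUNC_ITEMS]) - truth_vec)
        heck_err = np.abs(fit.earnings_coefficients[FUNC_ITEMS].to_numpy() - truth_vec)
        assert heck_err.mean() < naive_err.mean()

    def test_determinism(self, survey):
        f1, f2 = fit_heckman(survey), fit_heckman(survey)
        pd.testing.assert_series_equal(f1.earnings_coefficients,
                                       f2.earnings_coefficients)

    def test_all_employed_raises(self, survey):
        sub = survey[survey.employed == 1]
        with pytest.raises(EstimationError):
            fit_heckman(sub)

    def test_singular_stage2_raises(self, survey):
        dup = survey.copy()
        dup["func_dup"] = dup["func1"]
        spec = CovariateSpec(
            employment=["age", "func1", "other_income_flag"],
            earnings=["age", "func1", "func_dup"],
        )
        with pytest.raises(EstimationError):
            fit_heckman(dup, spec)

    def test_json_round_trip(self, heckman_fit, tmp_path):
        from thacea.heckman import HeckmanFit
        heckman_fit.to_json(tmp_path / "fit.json")
        back = HeckmanFit.from_json(tmp_path / "fit.json")
        pd.testing.assert_series_equal(back.earnings_coefficients,
                                       heckman_fit.earnings_coefficients)
        pd.testing.assert_frame_equal(back.probit_cov, heckman_fit.probit_cov)


class TestPooling:
    def test_identical_fits_pool_to_themselves(self, heckman_fit):
        pooled = pool_imputations([heckman_fit] * 3)
        pd.testing.assert_series_equal(pooled.earnings_coefficients,
                                       heckman_fit.earnings_coefficients)
        # zero between-imputation variance
        pd.testing.assert_frame_equal(pooled.earnings_cov.round(12),
                                      heckman_fit.earnings_cov.round(12))

    def test_rubin_between_variance_hand_computed_m2(self, heckman_fit):
        import copy
        a = heckman_fit
        b = copy.deepcopy(heckman_fit)
        delta = 0.2
        b.earnings_coefficients = b.earnings_coefficients.copy()
        b.earnings_coefficients["func1"] += delta
        pooled = pool_imputations([a, b])
        # between-variance for m=2: sum((x - mean)^2)/(m-1) = delta^2/2
        expected = (a.earnings_cov.loc["func1", "func1"]
                    + (1 + 0.5) * delta**2 / 2)
        assert pooled.earnings_cov.loc["func1", "func1"] == pytest.approx(expected)
        assert pooled.earnings_coefficients["func1"] == pytest.approx(
            a.earnings_coefficients["func1"] + delta / 2)

    def test_pooled_se_at_least_mean_within_se(self, truth):
        t = GroundTruth(missing_earnings_fraction=0.3)
        records, _ = generate_survey(1200, t, m_imputations=5, seed=24)
        fits = [fit_heckman(sub) for _, sub in records.groupby("imputation_id")]
        pooled = pool_imputations(fits)
        within = np.mean([f.earnings_cov.loc["func1", "func1"] for f in fits])
        assert pooled.earnings_cov.loc["func1", "func1"] >= within - 1e-12
        assert pooled.pooled and pooled.m == 5

    def test_layout_mismatch_raises(self, heckman_fit, survey):
        other = fit_heckman(survey, CovariateSpec(
            employment=["age", "func1", "other_income_flag"],
            earnings=["age", "func1"]))
        with pytest.raises(LayoutError):
            pool_imputations([heckman_fit, other])

    def test_imputed_dispatch_pools(self):
        t = GroundTruth(missing_earnings_fraction=0.3)
        records, _ = generate_survey(800, t, m_imputations=3, seed=25)
        fit = fit_heckman_imputed(records)
        assert fit.pooled and fit.m == 3


class TestPrediction:
    def _profile(self, **over):
        base = {"age": 50.0, "female": 0, "race_black": 0, "race_other": 0,
                "married": 1, "family_size": 2, "educ_somecol": 0,
                "educ_college": 1, "other_income_flag": 0,
                "other_worker_in_household": 1}
        base.update({f: 1 for f in FUNC_ITEMS})
        base.update(over)
        return base

    def test_probability_in_unit_interval(self, heckman_fit):
        for age in (20, 50, 90):
            for sev in (0, 4):
                cov = self._profile(age=age, **{f: sev for f in FUNC_ITEMS})
                assert 0 <= predict_employment_prob(heckman_fit, cov) <= 1

    def test_zero_index_gives_half(self, heckman_fit):
        import copy
        fit = copy.deepcopy(heckman_fit)
        fit.probit_coefficients[:] = 0.0
        assert predict_employment_prob(fit, self._profile()) == 0.5

    def test_worsening_items_strictly_decreases_employment(self, heckman_fit):
        probs = [predict_employment_prob(heckman_fit,
                                         self._profile(**{f: s for f in FUNC_ITEMS}))
                 for s in range(5)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_identical_inputs_identical_outputs(self, heckman_fit):
        cov = self._profile()
        assert (predict_employment_prob(heckman_fit, cov)
                == predict_employment_prob(heckman_fit, cov))

    def test_layout_mismatch_raises(self, heckman_fit):
        with pytest.raises(LayoutError):
            predict_employment_prob(heckman_fit, {"age": 50.0})


class TestExpectedProductivity:
    def test_zero_employment_gives_zero(self, heckman_fit):
        import copy
        fit = copy.deepcopy(heckman_fit)
        fit.probit_coefficients[:] = 0.0
        fit.probit_coefficients["const"] = -40.0
        cov = TestPrediction()._profile()
        assert expected_productivity(fit, cov) == pytest.approx(0.0, abs=1e-6)

    def test_definition_with_no_missed_days(self, heckman_fit):
        cov = TestPrediction()._profile()
        p = predict_employment_prob(heckman_fit, cov)
        e = predict_earnings(heckman_fit, cov)
        assert expected_productivity(heckman_fit, cov, 0.0) == pytest.approx(p * e)

    def test_full_year_absence_gives_zero(self, heckman_fit):
        cov = TestPrediction()._profile()
        assert expected_productivity(heckman_fit, cov, 250.0, 250.0) == 0.0

    def test_missed_days_outside_range_rejected(self, heckman_fit):
        cov = TestPrediction()._profile()
        with pytest.raises(ValueError):
            expected_productivity(heckman_fit, cov, 300.0, 250.0)
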