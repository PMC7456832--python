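"""Effect estimators: exact recoveries, algebraic identities, reductions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from seqmed._linalg import ols, wls
from seqmed.estimators import (EstimationSpec, doubly_robust_direct,
                               estimate_all_methods, estimate_total_effect,
                               estimates_frame, indirect_effect, ipw_direct,
                               one_confounder_battery,
                               regression_adjusted_direct, sequential_g_direct,
                               two_confounder_battery)
from tests.conftest import random_linear_dataset


class TestLeastSquaresHelpers:
    def test_ols_matches_statsmodels(self, medium_dataset):
        y = medium_dataset["Y"].to_numpy()
        cols = [medium_dataset[c].to_numpy() for c in ("X", "M", "C1")]
        coefs, sd = ols(y, cols)
        ref = sm.OLS(y, sm.add_constant(medium_dataset[["X", "M", "C1"]])).fit()
        np.testing.assert_allclose(coefs, ref.params.to_numpy(), rtol=1e-9)
        assert sd == pytest.approx(np.sqrt(ref.mse_resid), rel=1e-9)

    def test_wls_matches_statsmodels(self, medium_dataset):
        rng = np.random.default_rng(0)
        w = rng.lognormal(size=len(medium_dataset))
        y = medium_dataset["Y"].to_numpy()
        cols = [medium_dataset[c].to_numpy() for c in ("X", "M")]
        coefs = wls(y, cols, w)
        ref = sm.WLS(y, sm.add_constant(medium_dataset[["X", "M"]]),
                     weights=w).fit()
        np.testing.assert_allclose(coefs, ref.params.to_numpy(), rtol=1e-9)

    def test_collinear_design_rejected(self):
        from seqmed._linalg import DegenerateDesignError
        y = np.arange(10.0)
        x = np.arange(10.0)
        with pytest.raises(DegenerateDesignError):
            ols(y, [x, 2 * x])


class TestTotalEffect:
    def test_noise_free_total_effect_exact(self, noise_free_dataset):
        assert estimate_total_effect(noise_free_dataset) == pytest.approx(
            0.5481, abs=1e-12)

    def test_constant_outcome_gives_zero_slope(self):
        data = pd.DataFrame({"X": [0, 1, 0, 1], "M": [0.0, 1, 2, 3],
                             "Y": [2.0, 2, 2, 2]})
        assert estimate_total_effect(data) == pytest.approx(0.0, abs=1e-12)

    def test_single_arm_rejected(self):
        data = pd.DataFrame({"X": [1, 1, 1, 1], "M": [0.0, 1, 2, 3],
                             "Y": [0.0, 1, 2, 3]})
        with pytest.raises(ValueError, match="single treatment arm"):
            estimate_total_effect(data)


class TestRegressionAdjustment:
    def test_noise_free_exact_recovery(self, noise_free_dataset):
        est = regression_adjusted_direct(
            noise_free_dataset,
            EstimationSpec("regression", outcome_confounders=("C1",)))
        assert est.direct_hat == pytest.approx(0.2, abs=1e-12)
        assert est.b_hat == pytest.approx(0.59, abs=1e-12)
        assert est.indirect_hat == pytest.approx(est.total_hat - est.direct_hat)

    def test_difference_equals_product_without_confounders(self, medium_dataset):
        # OLS identity: c - c' = a_hat * b_hat when no covariates are adjusted
        est = regression_adjusted_direct(
            medium_dataset, EstimationSpec("regression"))
        assert est.indirect_hat == pytest.approx(est.a_hat * est.b_hat,
                                                 abs=1e-10)


class TestSequentialG:
    def test_noise_free_exact_recovery(self, noise_free_dataset):
        est = sequential_g_direct(
            noise_free_dataset,
            EstimationSpec("seq_g", outcome_confounders=("C1",)))
        assert est.b_hat == pytest.approx(0.59, abs=1e-12)
        assert est.direct_hat == pytest.approx(0.2, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_three_indirect_estimators_agree_without_confounders(self, seed):
        """Product-of-coefficients, difference-in-coefficients and the
        sequential g-estimate coincide algebraically when no confounders
        are modeled."""
        data = random_linear_dataset(np.random.default_rng(seed))
        reg = regression_adjusted_direct(data, EstimationSpec("regression"))
        seqg = sequential_g_direct(data, EstimationSpec("seq_g"))
        product = reg.a_hat * reg.b_hat
        assert abs(reg.indirect_hat - product) < 1e-10
        assert abs(seqg.indirect_hat - reg.indirect_hat) < 1e-10


class TestIPWAndDoublyRobust:
    def test_unit_weights_reduce_ipw_to_unadjusted_ols(self, medium_dataset):
        est = ipw_direct(medium_dataset, EstimationSpec("ipw"))
        y = medium_dataset["Y"].to_numpy()
        coefs, _ = ols(y, [medium_dataset["X"].to_numpy(),
                           medium_dataset["M"].to_numpy()])
        assert est.direct_hat == pytest.approx(float(coefs[1]), abs=1e-12)
        assert est.b_hat == pytest.approx(float(coefs[2]), abs=1e-12)

    def test_unit_weights_reduce_dr_to_sequential_g(self, medium_dataset):
        dr = doubly_robust_direct(
            medium_dataset,
            EstimationSpec("dr_seq_g", outcome_confounders=("C1", "C2")))
        seqg = sequential_g_direct(
            medium_dataset,
            EstimationSpec("seq_g", outcome_confounders=("C1", "C2")))
        assert dr.direct_hat == pytest.approx(seqg.direct_hat, abs=1e-12)
        assert dr.b_hat == pytest.approx(seqg.b_hat, abs=1e-12)

    def test_truncation_flag_changes_weights_not_model(self, medium_dataset):
        spec = EstimationSpec("ipw_truncated",
                              propensity_confounders=("C1", "C2"))
        plain = ipw_direct(medium_dataset, spec, truncate=False)
        trunc = ipw_direct(medium_dataset, spec, truncate=True)
        assert plain.total_hat == trunc.total_hat
        assert plain.direct_hat != trunc.direct_hat  # caps bind somewhere


class TestIndirectEffect:
    @pytest.mark.parametrize("total, direct, expected", [
        (1.0, 0.4, 0.6), (0.5481, 0.2, 0.3481), (0.7, 0.7, 0.0)])
    def test_subtraction(self, total, direct, expected):
        assert indirect_effect(total, direct) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            indirect_effect(float("nan"), 0.0)


class TestBatteries:
    def test_two_confounder_battery_yields_five_results(self, medium_dataset):
        ests = estimate_all_methods(medium_dataset, two_confounder_battery())
        assert len(ests) == 5
        assert [e.method for e in ests] == ["regression", "ipw",
                                            "ipw_truncated", "seq_g",
                                            "dr_seq_g"]
        assert len({e.total_hat for e in ests}) == 1  # shared total effect

    def test_one_confounder_battery_yields_seven_results(self, medium_dataset):
        ests = estimate_all_methods(medium_dataset, one_confounder_battery())
        assert len(ests) == 7
        labels = [e.label for e in ests]
        assert labels[-3:] == ["dr_seq_g_misspec_mediator",
                               "dr_seq_g_misspec_outcome",
                               "dr_seq_g_misspec_both"]

    def test_empty_battery_rejected(self, medium_dataset):
        with pytest.raises(ValueError):
            estimate_all_methods(medium_dataset, [])

    def test_estimates_frame_has_export_header(self, medium_dataset):
        frame = estimates_frame(
            estimate_all_methods(medium_dataset, two_confounder_battery()))
        assert list(frame.columns) == ["method", "spec_label", "total_hat",
                                       "direct_hat", "indirect_hat", "b_hat",
                                       "a_hat"]
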