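"""Dose-response fitting, smoothing, and Bliss/HSA synergy scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combotrans.dose_response import (CombinationMatrix, fit_dose_response,
                                      log_logistic, single_agent_metrics,
                                      smooth_combination_matrix, synergy_analysis,
                                      top_fraction_score)
from combotrans.errors import FitError, MarginError, ParameterError

NINE_POINT = 10.0 * (1.0 / 3.0) ** np.arange(9)[::-1]  # 1:3 dilution from 10 µM


class TestFit:
    def test_noiseless_roundtrip_recovers_parameters(self):
        v = log_logistic(NINE_POINT, 1.0, 0.1, 0.05, 1.5)
        c = fit_dose_response(NINE_POINT, v, "LL.4")
        assert c.upper_limit == pytest.approx(1.0, rel=1e-6)
        assert c.lower_limit == pytest.approx(0.1, rel=1e-6)
        assert c.ec50 == pytest.approx(0.05, rel=1e-6)
        assert c.hill == pytest.approx(1.5, rel=1e-6)

    def test_flat_viability_has_no_ic50_and_zero_auc(self):
        c = fit_dose_response(NINE_POINT, np.ones(9))
        assert c.ic50_abs is None
        assert c.emax == pytest.approx(1.0, abs=1e-9)
        assert c.auc == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_curve_crosses_half_at_ec50(self):
        v = 1.0 / (1.0 + NINE_POINT / 0.1)
        c = fit_dose_response(NINE_POINT, v, "LL.4")
        assert c.ic50_abs == pytest.approx(0.1, rel=1e-6)

    def test_too_few_doses_raises(self):
        with pytest.raises(FitError):
            fit_dose_response([0.1, 1.0, 10.0], [0.9, 0.5, 0.2])

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(42)
        truth = np.array([1.0, 0.1, 0.05, 1.5])
        rel_errs = []
        for _ in range(100):
            v = log_logistic(NINE_POINT, *truth) * np.exp(
                rng.normal(0, 0.02, NINE_POINT.shape))
            c = fit_dose_response(NINE_POINT, v, "LL.4")
            est = np.array([c.upper_limit, c.lower_limit, c.ec50, c.hill])
            rel_errs.append(np.abs(est - truth) / truth)
        assert np.median(np.stack(rel_errs), axis=0).max() < 0.05

    def test_floor_above_half_has_no_ic50(self):
        v = log_logistic(NINE_POINT, 1.0, 0.6, 0.1, 1.5)
        c = fit_dose_response(NINE_POINT, v, "LL.4")
        assert c.ic50_abs is None


class TestSingleAgentMetrics:
    def test_ic50_within_range(self):
        v = log_logistic(NINE_POINT, 1.0, 0.0, 0.1, 1.0)
        c = fit_dose_response(NINE_POINT, v, "LL.4")
        m = single_agent_metrics(c, (0.001, 10.0))
        assert m["ic50_abs"] == pytest.approx(0.1, rel=1e-4)

    def test_auc_bounds_for_flat_curves(self):
        c1 = fit_dose_response(NINE_POINT, np.ones(9))
        assert single_agent_metrics(c1, (0.01, 10))["auc"] == pytest.approx(0, abs=1e-9)
        c0 = fit_dose_response(NINE_POINT, np.full(9, 1e-9), "LL.4")
        assert single_agent_metrics(c0, (0.01, 10))["auc"] == pytest.approx(1, abs=1e-3)

    def test_empty_range_raises(self):
        v = log_logistic(NINE_POINT, 1.0, 0.0, 0.1, 1.0)
        c = fit_dose_response(NINE_POINT, v, "LL.4")
        with pytest.raises(ParameterError):
            single_agent_metrics(c, (1.0, 1.0))


class TestSmoothing:
    def test_constant_matrix_unchanged(self, half_log_grids):
        da, db = half_log_grids
        m = CombinationMatrix("a", "b", da, db, np.full((9, 9), 0.7))
        assert np.allclose(smooth_combination_matrix(m), 0.7, atol=1e-6)

    def test_separable_surface_is_fixed_point(self, independent_matrix):
        out = smooth_combination_matrix(independent_matrix)
        assert np.abs(out - independent_matrix.viability).max() < 1e-3

    def test_smoothing_reduces_noise(self, independent_matrix):
        rng = np.random.default_rng(7)
        true = independent_matrix.viability
        se_obs = se_smooth = 0.0
        for _ in range(30):
            noisy = true * np.exp(rng.normal(0, 0.05, true.shape))
            m = CombinationMatrix("a", "b", independent_matrix.doses_a,
                                  independent_matrix.doses_b, noisy)
            sm = smooth_combination_matrix(m)
            se_obs += np.sum((noisy - true) ** 2)
            se_smooth += np.sum((sm - true) ** 2)
        assert se_smooth < se_obs


class TestSynergy:
    def test_bliss_and_hsa_excess_single_cell(self):
        # margins rA = rB = 0.5, combined response 0.75 = exact independence
        da = np.array([0.0, 0.1])
        db = np.array([0.0, 0.1])
        v = np.array([[1.0, 0.5], [0.5, 0.25]])
        m = CombinationMatrix("a", "b", da, db, v)
        res = synergy_analysis(m, smooth=False)
        assert res.bliss_excess[1, 1] == pytest.approx(0.0, abs=1e-12)
        assert res.hsa_excess[1, 1] == pytest.approx(0.25, abs=1e-12)

    def test_one_hot_top_ten_percent_score(self):
        excess = np.zeros((10, 10))
        excess[3, 4] = 0.5
        assert top_fraction_score(excess, 0.10) == pytest.approx(0.05, abs=1e-15)

    def test_independent_matrix_scores_zero(self, independent_matrix):
        res = synergy_analysis(independent_matrix)
        assert abs(res.bliss_score) < 5e-3

    def test_expectations_match_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            v = np.clip(rng.uniform(0, 1.1, (5, 5)), 0, None)
            v[0, 0] = 1.0
            m = CombinationMatrix("a", "b", np.array([0, 0.1, 0.3, 1, 3.0]),
                                  np.array([0, 0.1, 0.3, 1, 3.0]), v)
            res = synergy_analysis(m, smooth=False)
            r = 1 - np.clip(v, 0, 1)
            for i in range(5):
                for j in range(5):
                    ra, rb = r[i, 0], r[0, j]
                    assert res.bliss_expectation[i, j] == pytest.approx(
                        ra + rb - ra * rb, abs=1e-12)
                    assert res.hsa_expectation[i, j] == pytest.approx(
                        max(ra, rb), abs=1e-12)

    def test_hsa_expectation_below_bliss_expectation(self, independent_matrix):
        res = synergy_analysis(independent_matrix)
        assert np.all(res.hsa_expectation <= res.bliss_expectation + 1e-12)

    def test_scores_invariant_under_transpose(self, independent_matrix):
        res = synergy_analysis(independent_matrix)
        res_t = synergy_analysis(independent_matrix.transpose())
        assert res.bliss_score == pytest.approx(res_t.bliss_score, abs=1e-9)
        assert res.hsa_score == pytest.approx(res_t.hsa_score, abs=1e-9)

    def test_missing_margins_raises(self, half_log_grids):
        da, db = half_log_grids
        m = CombinationMatrix("a", "b", da[1:], db[1:], np.ones((8, 8)) * 0.5)
        with pytest.raises(MarginError):
            synergy_analysis(m)

    def test_bad_top_fraction_raises(self, independent_matrix):
        with pytest.raises(ParameterError):
            synergy_analysis(independent_matrix, top_fraction=1.5)


@settings(derandomize=True, max_examples=60)
@given(ra=st.floats(0, 1), rb=st.floats(0, 1))
def test_bliss_expectation_algebraic_properties(ra, rb):
    """Symmetric; identity at 0; saturates at 1; within [max(ra,rb), 1]."""
    bliss = ra + rb - ra * rb
    assert bliss == pytest.approx(rb + ra - rb * ra)
    assert bliss >= max(ra, rb) - 1e-12
    assert bliss <= 1.0 + 1e-12
    assert (ra + 0 - 0) == pytest.approx(ra)
    if ra == 1 or rb == 1:
        assert bliss == pytest.approx(1.0)


def test_matrix_validation_rejects_bad_shapes():
    with pytest.raises(ParameterError):
        CombinationMatrix("a", "b", np.array([0, 1.0]), np.array([0, 1.0]),
                          np.ones((3, 2))).validate()
    with pytest.raises(ParameterError):
        CombinationMatrix("a", "b", np.array([1.0, 0.5]), np.array([0, 1.0]),
                          np.ones((2, 2))).validate()
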