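"""GR metric, free-dose conversion, interpolation, and tumor prediction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from combotrans import gr
from combotrans.errors import ParameterError


class TestGRMetric:
    def test_untreated_viability_gives_gr_one(self):
        assert gr.viability_to_gr(1.0, 120, 60) == pytest.approx(1.0)

    def test_static_cells_give_gr_zero(self):
        # treated cells exactly static: v = 2^(-T/Td)
        v = 2.0 ** (-120.0 / 60.0)
        assert gr.viability_to_gr(v, 120, 60) == pytest.approx(0.0, abs=1e-12)

    def test_half_viability_closed_form(self):
        assert gr.viability_to_gr(0.5, 120, 60) == pytest.approx(2 ** 0.5 - 1)

    def test_rate_conversion_fixed_points(self):
        assert gr.gr_to_normalized_rate(1.0) == pytest.approx(1.0)
        assert gr.gr_to_normalized_rate(0.0) == pytest.approx(0.0)
        assert gr.gr_to_normalized_rate(-0.5) == pytest.approx(-1.0)

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            gr.viability_to_gr(0.0, 120, 60)
        with pytest.raises(ParameterError):
            gr.gr_to_normalized_rate(-1.0)

    @settings(derandomize=True, max_examples=50)
    @given(v=st.floats(1e-3, 1.2), td=st.floats(10, 120), t=st.floats(48, 240))
    def test_composition_identity(self, v, td, t):
        """r_norm(GR(v)) = 1 + log2(v) Td/T for any valid viability."""
        r = gr.gr_to_normalized_rate(gr.viability_to_gr(v, t, td))
        assert r == pytest.approx(1 + math.log2(v) * td / t, rel=1e-6, abs=1e-6)


class TestFreeDose:
    def test_belvarafenib_media_fu(self):
        assert gr.nominal_to_free(1.0, 0.034) == pytest.approx(0.034)

    def test_zero_dose(self):
        assert gr.nominal_to_free(0.0, 0.196) == 0.0

    def test_cobimetinib_product(self):
        assert gr.nominal_to_free(0.5, 0.196) == pytest.approx(0.098)

    def test_invalid_fu(self):
        with pytest.raises(ParameterError):
            gr.nominal_to_free(1.0, 0.0)


class TestInterpolation:
    def test_grid_node_identity(self):
        da = np.array([0.0, 0.01, 0.1, 1.0])
        db = np.array([0.0, 0.02, 0.2, 2.0])
        vals = np.arange(16.0).reshape(4, 4)
        for i, a in enumerate(da):
            for j, b in enumerate(db):
                got = gr.interpolate_surface(da, db, vals, a, b)
                assert got == pytest.approx(vals[i, j], abs=1e-9)

    def test_bilinear_reproduces_log_plane(self):
        da = np.array([0.0, 0.01, 0.1, 1.0])
        db = np.array([0.0, 0.01, 0.1, 1.0])
        plane = (2.0 + 3.0 * np.log10(np.maximum(da, 1e-6))[:, None]
                 + 0.5 * np.log10(np.maximum(db, 1e-6))[None, :])
        for qa, qb in [(0.03, 0.5), (0.02, 0.02), (0.5, 0.011)]:
            expect = 2.0 + 3.0 * math.log10(qa) + 0.5 * math.log10(qb)
            got = gr.interpolate_surface(da, db, plane, qa, qb)
            assert got == pytest.approx(expect, rel=1e-9)

    def test_log_midpoint_of_symmetric_corners(self):
        da = np.array([0.01, 0.1])
        db = np.array([0.01, 0.1])
        vals = np.array([[0.0, 1.0], [1.0, 2.0]])
        mid = 10 ** -1.5
        assert gr.interpolate_surface(da, db, vals, mid, mid) == pytest.approx(1.0)

    def test_linear_bridge_below_grid_minimum(self):
        da = np.array([0.0, 0.1, 1.0])
        db = np.array([0.0, 0.1, 1.0])
        vals = np.array([[1.0, 0.8, 0.6], [0.9, 0.7, 0.5], [0.5, 0.3, 0.1]])
        # halfway (in linear dose) between 0 and 0.1 along axis a, at b = 0
        got = gr.interpolate_surface(da, db, vals, 0.05, 0.0)
        assert got == pytest.approx(0.5 * (1.0 + 0.9))

    def test_queries_above_grid_clamp(self):
        da = np.array([0.0, 0.1, 1.0])
        db = np.array([0.0, 0.1, 1.0])
        vals = np.ones((3, 3)) * np.array([1.0, 0.7, 0.4])
        assert gr.interpolate_surface(da, db, vals, 5.0, 5.0) == pytest.approx(0.4)

    def test_agrees_with_tensor_product_oracle(self):
        """Interior queries must match an independent tensor-product oracle
        built from np.interp in log10-dose space on random smooth surfaces."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            da = np.concatenate([[0.0], np.logspace(-2, 0, 5)])
            db = np.concatenate([[0.0], np.logspace(-2, 0, 5)])
            coef = rng.normal(size=3)
            la = np.log10(da[1:])
            lb = np.log10(db[1:])
            vals = rng.normal(size=(6, 6))
            vals[1:, 1:] = (coef[0] + coef[1] * la[:, None] + coef[2] * lb[None, :]
                            + 0.3 * np.sin(la)[:, None] * np.cos(lb)[None, :])
            qa, qb = 10 ** rng.uniform(-1.9, -0.1, 2)
            direct = gr.interpolate_surface(da, db, vals, qa, qb)
            rows = np.array([np.interp(np.log10(qb), lb, vals[i, 1:])
                             for i in range(1, 6)])
            oracle = float(np.interp(np.log10(qa), la, rows))
            assert direct == pytest.approx(oracle, rel=1e-9, abs=1e-9)


class TestTumorPrediction:
    def test_paper_baseline_rate(self):
        assert gr.baseline_rate_from_doubling(18.0) == pytest.approx(0.0385, abs=5e-5)

    def test_unit_doubling(self):
        assert gr.baseline_rate_from_doubling(math.log(2)) == pytest.approx(1.0)

    def test_cytostasis_keeps_volume_constant(self):
        pred = gr.predict_tumor_growth(240, 0.0385, 0.0, [0, 7, 14, 21])
        assert np.allclose(pred.predicted_volumes, 240.0)

    def test_control_doubles_in_one_doubling_time(self):
        k = gr.baseline_rate_from_doubling(18.0)
        pred = gr.predict_tumor_growth(100.0, k, 1.0, [18.0])
        assert pred.predicted_volumes[0] == pytest.approx(200.0, rel=1e-9)

    def test_regressing_arm_closed_form(self):
        pred = gr.predict_tumor_growth(240.0, 0.0385, -0.5, [21.0])
        assert pred.predicted_volumes[0] == pytest.approx(
            240.0 * math.exp(-0.5 * 0.0385 * 21.0), rel=1e-12)


class TestBenchFormulas:
    def test_caliper_volume(self):
        assert gr.caliper_volume(10, 10) == pytest.approx(500.0)
        assert gr.caliper_volume(20, 10) == pytest.approx(1000.0)
        assert gr.caliper_volume(15.9, 12.3) == pytest.approx(1202.8, abs=0.05)

    def test_caliper_argument_order(self):
        with pytest.raises(ParameterError):
            gr.caliper_volume(10, 20)

    def test_body_weight_change_and_flag(self):
        assert gr.body_weight_change(22, 22) == (pytest.approx(0.0), False)
        pct, flag = gr.body_weight_change(17.6, 22)
        assert pct == pytest.approx(-20.0) and flag
        pct, flag = gr.body_weight_change(24.2, 22)
        assert pct == pytest.approx(10.0) and not flag

    def test_ddct_fold_change(self):
        assert gr.ddct_fold_change(0) == pytest.approx(1.0)
        assert gr.ddct_fold_change(1) == pytest.approx(0.5)
        assert gr.ddct_fold_change(-2) == pytest.approx(4.0)


def test_gr_surface_from_matrix_margins(independent_matrix):
    consts = gr.AssayConstants()
    surf = gr.gr_surface_from_matrix(independent_matrix, consts)
    assert surf.free_doses_a[-1] == pytest.approx(10.0 * 0.034)
    assert surf.gr[0, 0] == pytest.approx(1.0, abs=1e-6)  # untreated cell
    # normalized rate relates elementwise as log2(GR + 1)
    assert np.allclose(surf.normalized_rate, np.log2(surf.gr + 1))
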