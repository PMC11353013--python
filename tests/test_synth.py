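"""Synthetic-data generators: determinism, ground truth, recovery."""

from dataclasses import replace

import numpy as np
import pytest

from combotrans import synth
from combotrans.dose_response import log_logistic, synergy_analysis
from combotrans.errors import ParameterError
from combotrans.tgi import fit_tgi


@pytest.fixture
def grids(half_log_grids):
    return half_log_grids


MARGIN_A = (1.0, 0.1, 0.3, 1.5)
MARGIN_B = (1.0, 0.2, 0.05, 1.2)


class TestViabilityMatrix:
    def test_zero_amplitude_zero_noise_is_bliss_independent(self, grids):
        da, db = grids
        m, _ = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db)
        res = synergy_analysis(m)
        assert abs(res.bliss_score) < 5e-3

    def test_bump_score_matches_generator_oracle(self, grids):
        """With a noiseless bump, the Bliss excess of the raw surface equals
        the generating Gaussian, so the raw-score equals the top-k mean of
        the constructed bump values."""
        da, db = grids
        center = (np.sqrt(da[1] * da[-1]), np.sqrt(db[1] * db[-1]))
        bump = {"amplitude": 0.3, "center": center, "width": 0.5}
        m, truth = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db,
                                                   bump=bump)
        res = synergy_analysis(m, smooth=False)
        g = synth._gaussian_bump(da, db, 0.3, center, 0.5)
        # direct evaluation of the generating formula (truncation-aware)
        va = log_logistic(da, *MARGIN_A)
        vb = log_logistic(db, *MARGIN_B)
        expected_excess = np.minimum(g, va[:, None] * vb[None, :])
        k = int(np.ceil(0.1 * g.size))
        top = np.sort(expected_excess.ravel())[-k:]
        assert res.bliss_score == pytest.approx(top.mean(), abs=1e-9)

    def test_seed_determinism(self, grids):
        da, db = grids
        m1, _ = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db,
                                                noise_sd=0.05, seed=3)
        m2, _ = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db,
                                                noise_sd=0.05, seed=3)
        m3, _ = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db,
                                                noise_sd=0.05, seed=4)
        assert np.array_equal(m1.viability, m2.viability)
        assert not np.array_equal(m1.viability, m3.viability)

    def test_generated_matrix_satisfies_invariants(self, grids):
        da, db = grids
        m, _ = synth.generate_viability_matrix(MARGIN_A, MARGIN_B, da, db,
                                               noise_sd=0.05, seed=0)
        m.validate()


class TestScreenPanel:
    def test_group_contrast_with_explicit_amplitudes(self):
        """BRAF-like amplitude 0 vs NRAS-like amplitude 0.3 must separate
        the group-mean Bliss scores by more than 0.1."""
        groups = {
            "BRAF_V600": replace(synth.DEFAULT_PANEL_SPEC.groups["BRAF_V600"],
                                 n_lines=4, bump_amplitude_mean=0.0,
                                 bump_amplitude_sd=0.0),
            "NRAS_Q61": replace(synth.DEFAULT_PANEL_SPEC.groups["NRAS_Q61"],
                                n_lines=4, bump_amplitude_mean=0.3,
                                bump_amplitude_sd=0.0),
        }
        spec = synth.PanelSpec(groups=groups, noise_sd=0.02)
        scores = {"BRAF_V600": [], "NRAS_Q61": []}
        for seed in range(3):
            mats, truth = synth.generate_screen_panel(spec, seed=seed)
            for m, t in zip(mats, truth.per_item):
                scores[t["group"]].append(synergy_analysis(m).bliss_score)
        diff = np.mean(scores["NRAS_Q61"]) - np.mean(scores["BRAF_V600"])
        assert diff > 0.1

    def test_panel_size_and_ground_truth_alignment(self):
        mats, truth = synth.generate_screen_panel(seed=0)
        assert len(mats) == 43
        assert len(truth.per_item) == 43
        assert all(m.cell_line == t["cell_line"]
                   for m, t in zip(mats, truth.per_item))

    def test_empty_panel(self):
        groups = {g: replace(s, n_lines=0)
                  for g, s in synth.DEFAULT_PANEL_SPEC.groups.items()}
        mats, truth = synth.generate_screen_panel(
            synth.PanelSpec(groups=groups), seed=0)
        assert mats == []


class TestXenograftVolumes:
    def test_noiseless_doubling(self):
        days, vols = synth.generate_xenograft_volumes(
            240.0, np.log(2) / 18.0, days=(0, 18), seed=0)
        assert vols[1] == pytest.approx(480.0, rel=1e-12)

    def test_rate_recovery_by_log_linear_regression(self):
        days, vols = synth.generate_xenograft_volumes(240.0, 0.0385, seed=0)
        slope = np.polyfit(days, np.log(vols), 1)[0]
        assert slope == pytest.approx(0.0385, rel=1e-10)

    def test_negative_rate_strictly_decreasing(self):
        _, vols = synth.generate_xenograft_volumes(240.0, -0.05, seed=0)
        assert np.all(np.diff(vols) < 0)


class TestTGICohort:
    def test_noiseless_per_subject_recovery(self):
        recs, truth = synth.generate_tgi_cohort(
            4, {"NRAS": (0.05, 0.2)}, obs_weeks=np.arange(0.0, 52.0, 2.0),
            noise_sd=0.0, seed=1)
        for rec, tr in zip(recs, truth.per_item):
            fit = fit_tgi(rec["weeks"], rec["sizes"])
            assert fit.kg == pytest.approx(tr["params"].kg, rel=1e-4)
            assert fit.ks == pytest.approx(tr["params"].ks, rel=1e-4)

    def test_group_means_recovered_within_three_se(self):
        recs, truth = synth.generate_tgi_cohort(
            100, {"g": (0.05, 0.2)}, noise_sd=0.05, log_sd=0.3, seed=2)
        kgs = np.array([fit_tgi(r["weeks"], r["sizes"]).kg for r in recs])
        true_kgs = np.array([t["params"].kg for t in truth.per_item])
        se = true_kgs.std() / np.sqrt(len(true_kgs))
        assert abs(np.mean(kgs) - np.mean(true_kgs)) < 3 * se

    def test_single_subject_no_noise(self):
        recs, truth = synth.generate_tgi_cohort(1, {"g": (0.05, 0.2)},
                                                noise_sd=0.0, seed=3)
        p = truth.per_item[0]["params"]
        from combotrans.tgi import simulate_tumor_size
        assert np.allclose(recs[0]["sizes"],
                           simulate_tumor_size(p, recs[0]["weeks"]))

    def test_invalid_subject_count(self):
        with pytest.raises(ParameterError):
            synth.generate_tgi_cohort(0, {"g": (0.05, 0.2)})
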