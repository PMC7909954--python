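"""Generator contracts: determinism, zero-noise exactness, embedded truth."""

import numpy as np
import pandas as pd
import pytest

from gpcrbias.binding import CompetitionBinding
from gpcrbias.contacts import contact_occupancy
from gpcrbias.doseresponse import operational_response
from gpcrbias.invivo import percent_mpe
from gpcrbias.simulate import (
    BIAS_PANEL_CONCENTRATIONS,
    AssayDesign,
    TruthRecord,
    gen_bias_panel,
    gen_competition_binding,
    gen_conc_response,
    gen_distance_trajectory,
    gen_tailflick,
    half_log_concentrations,
    make_biased_truths,
)


def test_half_log_spacing():
    c = half_log_concentrations(1e-12, 1e-5)
    assert len(c) == 15
    np.testing.assert_allclose(np.diff(np.log10(c)), 0.5, atol=1e-12)
    assert len(BIAS_PANEL_CONCENTRATIONS) == 8


class TestAssayDesign:
    def test_rejects_nonpositive_concentrations(self):
        with pytest.raises(ValueError):
            AssayDesign(concentrations=np.array([0.0, 1e-9, 1e-8]))

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            AssayDesign(concentrations=np.array([1e-8, 1e-9]))

    def test_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            AssayDesign(noise_sd=-1.0)


class TestConcResponseGenerator:
    def test_zero_noise_equals_model_exactly(self, noise_free_design):
        truth = TruthRecord("x", "gprotein", tau=3.0, ka=2e-8)
        panel = gen_conc_response(truth, noise_free_design)
        expected = operational_response(
            panel.data["concentration_M"].to_numpy(), 100.0, 3.0, 2e-8)
        np.testing.assert_allclose(panel.data["response"], expected, rtol=0, atol=0)

    def test_half_maximal_point_of_operational_model(self, noise_free_design):
        # tau=1e6, K_A=1e-3 M: at A = K_A/tau = 1 nM the response sits at
        # half the system maximum
        truth = TruthRecord("x", "gprotein", tau=1e6, ka=1e-3)
        mean = operational_response(1e-9, truth.em, truth.tau, truth.ka)
        assert mean == pytest.approx(50.0, abs=1e-3)

    def test_same_seed_bit_identical(self, default_design):
        truth = TruthRecord("x", "gprotein", tau=5.0, ka=1e-8)
        a = gen_conc_response(truth, default_design)
        b = gen_conc_response(truth, default_design)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_same_truth(self, default_design):
        truth = TruthRecord("x", "gprotein", tau=5.0, ka=1e-8)
        a = gen_conc_response(truth, default_design)
        other = AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS.copy(), seed=99)
        b = gen_conc_response(truth, other)
        assert a.truth == b.truth
        assert not np.allclose(a.data["response"], b.data["response"])

    def test_monte_carlo_mean_converges_to_model(self):
        truth = TruthRecord("x", "gprotein", tau=2.0, ka=1e-8)
        design = AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS.copy(),
                             replicates_per_conc=200, n_experiments=1,
                             noise_sd=5.0, seed=11)
        panel = gen_conc_response(truth, design)
        means = panel.mean_by_concentration()
        model = operational_response(means.index.to_numpy(), 100.0, 2.0, 1e-8)
        se = 5.0 / np.sqrt(200)
        assert np.all(np.abs(means.to_numpy() - model) < 4 * se)

    def test_rejects_nonpositive_concentration(self, default_design):
        with pytest.raises(ValueError):
            truth = TruthRecord("x", "gprotein", tau=1.0, ka=-1e-8)
            gen_conc_response(truth, default_design)


class TestBiasPanelGenerator:
    @pytest.mark.parametrize("bf,expected_ddlog", [
        (1.0, 0.0),
        (10.0, 1.0),
        (22.0, np.log10(22.0)),  # = 1.3424
    ])
    def test_embedded_ddlog_matches_requested_bias(self, reference_truth,
                                                   default_design, bf, expected_ddlog):
        panels = gen_bias_panel(reference_truth, {"T": bf}, design=default_design)
        by_key = {(p.ligand, p.pathway): p.truth for p in panels}
        ddlog = ((by_key[("T", "gprotein")]["log_r"] - by_key[("REF", "gprotein")]["log_r"])
                 - (by_key[("T", "arrestin")]["log_r"] - by_key[("REF", "arrestin")]["log_r"]))
        assert ddlog == pytest.approx(expected_ddlog, abs=1e-12)

    def test_fewer_than_two_pathways_rejected(self, reference_truth, default_design):
        with pytest.raises(ValueError):
            gen_bias_panel(reference_truth, {"T": 10.0}, pathways=("gprotein",),
                           design=default_design)

    def test_panels_cover_all_ligand_pathway_pairs(self, reference_truth, default_design):
        panels = gen_bias_panel(reference_truth, {"A": 5.0, "B": 0.2},
                                design=default_design)
        keys = {(p.ligand, p.pathway) for p in panels}
        assert keys == {(l, p) for l in ("REF", "A", "B")
                        for p in ("gprotein", "arrestin")}

    def test_make_biased_truths_preserves_gprotein_side(self, reference_truth):
        ref = {"gprotein": reference_truth,
               "arrestin": TruthRecord("REF", "arrestin", tau=100.0, ka=1e-7)}
        truths = make_biased_truths(ref, 22.0, "T")
        assert truths["gprotein"].tau == reference_truth.tau
        assert truths["gprotein"].ka == reference_truth.ka


class TestCompetitionBindingGenerator:
    def test_hot_ligand_dilution_limit_gives_ic50_equal_ki(self, noise_free_design):
        panel = gen_competition_binding(1e-9, 1e-10, 1e-16, noise_free_design)
        assert panel.truth["ic50"] == pytest.approx(1e-9, rel=1e-5)

    def test_equal_hot_conc_and_kd_doubles_ic50(self, noise_free_design):
        panel = gen_competition_binding(1e-10, 1e-10, 1e-10, noise_free_design)
        assert panel.truth["ic50"] == pytest.approx(2e-10, rel=1e-12)

    def test_noise_free_round_trip_recovers_ki(self, noise_free_design):
        panel = gen_competition_binding(1e-9, 1e-10, 1e-10, noise_free_design)
        res = CompetitionBinding(panel).fit()
        assert res.converged
        assert res.ki == pytest.approx(1e-9, rel=1e-6)

    def test_rejects_nonpositive_hot_ligand(self, noise_free_design):
        with pytest.raises(ValueError):
            gen_competition_binding(1e-9, 1e-10, 0.0, noise_free_design)


class TestTailflickGenerator:
    def test_saturating_dose_censors_at_cutoff(self):
        lat = gen_tailflick(1.0, 2.0, [1e6], n_mice=4, mpe_noise_sd=0.0, seed=0)
        assert np.allclose(lat.data["test_s"], 15.0)

    def test_ed50_dose_gives_half_maximal_mpe(self):
        lat = gen_tailflick(10.0, 1.0, [10.0], n_mice=4, mpe_noise_sd=0.0, seed=0)
        mpe = percent_mpe(lat.data["test_s"].to_numpy(),
                          lat.data["baseline_s"].to_numpy())
        np.testing.assert_allclose(mpe, 50.0, atol=1e-9)

    def test_seeded_run_reproducible(self):
        a = gen_tailflick(6.1, 1.0, [1, 3, 10, 30, 100], n_mice=8, seed=42)
        b = gen_tailflick(6.1, 1.0, [1, 3, 10, 30, 100], n_mice=8, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_too_few_mice_rejected(self):
        with pytest.raises(ValueError):
            gen_tailflick(6.1, 1.0, [1, 3, 10], n_mice=1, seed=0)


class TestDistanceTrajectoryGenerator:
    def test_full_contact_probability(self):
        runs = gen_distance_trajectory(1.0, n_frames=200, n_runs=1, seed=0)
        occ = contact_occupancy(runs)
        assert occ.cumulative["either"] == 1.0

    def test_stationary_occupancy_recovered(self):
        p, n_frames, n_runs, rate = 0.5, 5000, 2, 0.1
        runs = gen_distance_trajectory(p, n_frames=n_frames, n_runs=n_runs,
                                       seed=7, switch_rate=rate)
        occ = contact_occupancy(runs)
        # Markov-chain SE: binomial SE inflated by the integrated
        # autocorrelation (1+lam)/(1-lam), lam = 1 - switch_rate
        lam = 1.0 - rate
        n_tot = n_frames * n_runs
        se = np.sqrt(p * (1 - p) / n_tot * (1 + lam) / (1 - lam))
        assert abs(occ.cumulative["either"] - p) < 3 * se

    def test_two_runs_share_parameters_but_differ(self):
        runs = gen_distance_trajectory(0.5, n_frames=100, n_runs=2, seed=1)
        assert [r.run_id for r in runs] == ["run1", "run2"]
        assert runs[0].residues == runs[1].residues
        assert not np.allclose(runs[0].distances["E209"], runs[1].distances["E209"])

    def test_distances_floored(self):
        runs = gen_distance_trajectory(1.0, n_frames=500, n_runs=1, seed=3,
                                       mean_in_A=1.4, sd_in_A=0.5)
        assert runs[0].distances["E209"].min() >= 1.5

    def test_short_run_rejected(self):
        with pytest.raises(ValueError):
            gen_distance_trajectory(0.5, n_frames=5, seed=0)
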