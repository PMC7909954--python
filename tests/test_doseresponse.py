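"""Logistic and operational fits, normalisation, BRET ratio, signal screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gpcrbias.doseresponse import (
    LogisticCurve,
    OperationalModel,
    bret_ratio,
    logistic3,
    logistic_to_logR,
    low_signal_check,
    mask_biphasic,
    normalize_to_reference,
    operational_response,
)
from gpcrbias.panels import ConcResponsePanel
from gpcrbias.simulate import (
    BIAS_PANEL_CONCENTRATIONS,
    AssayDesign,
    TruthRecord,
    gen_conc_response,
)


def make_panel(conc, resp, ligand="x", pathway="gprotein"):
    n = len(conc)
    data = pd.DataFrame({"experiment": [1] * n, "replicate": [1] * n,
                         "concentration_M": conc, "response": resp})
    return ConcResponsePanel(ligand, "REC", pathway, data)


class TestOperationalResponse:
    def test_zero_concentration_gives_zero(self):
        assert operational_response(0.0, 100.0, 5.0, 1e-8) == 0.0

    def test_tau_one_at_ka_gives_third_of_em(self):
        # E = Em*tau*A/(A*(1+tau)+K_A); tau=1, A=K_A -> Em/3
        assert operational_response(1e-8, 99.0, 1.0, 1e-8) == pytest.approx(33.0)

    def test_asymptote_is_em_tau_over_one_plus_tau(self):
        val = operational_response(10.0, 100.0, 3.0, 1e-8)
        assert val == pytest.approx(100.0 * 3.0 / 4.0, rel=1e-8)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            operational_response(-1e-9, 100.0, 1.0, 1e-8)


class TestLogisticToLogR:
    def test_full_agonist_limit(self):
        assert logistic_to_logR(100.0, 1e-9, 100.0) == pytest.approx(9.0)

    def test_partial_agonist(self):
        assert logistic_to_logR(50.0, 1e-9, 100.0) == pytest.approx(8.69897, abs=1e-5)

    def test_degenerate_emax_rejected(self):
        with pytest.raises(ValueError):
            logistic_to_logR(0.0, 1e-9, 100.0)
        with pytest.raises(ValueError):
            logistic_to_logR(120.0, 1e-9, 100.0)


class TestLogisticCurve:
    def test_exact_recovery_on_noise_free_data(self):
        x = np.linspace(-12, -6, 13)
        y = logistic3(x, 0.0, 100.0, -9.0)
        fit = LogisticCurve(10.0**x, y).fit()
        assert fit.converged
        assert fit.logec50 == pytest.approx(-9.0, abs=1e-6)
        assert fit.top == pytest.approx(100.0, abs=1e-6)
        assert fit.top >= fit.bottom

    def test_refuses_fewer_than_four_concentrations(self):
        with pytest.raises(ValueError):
            LogisticCurve([1e-9, 1e-8, 1e-7], [1, 50, 99])

    def test_flat_data_flagged_not_raised(self):
        conc = 10.0 ** np.linspace(-10, -6, 8)
        fit = LogisticCurve(conc, np.zeros(8)).fit()
        assert not fit.converged or fit.span < 1e-6

    def test_noisy_recovery_within_tolerance(self):
        # seeded noisy panels: logEC50 within +/-0.15 of truth in >=95% of runs
        hits = 0
        n_rep = 120
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            conc = BIAS_PANEL_CONCENTRATIONS
            y = np.concatenate([
                logistic3(np.log10(conc), 0.0, 100.0, -8.0) + rng.normal(0, 5.0, len(conc))
                for _ in range(3)
            ])
            fit = LogisticCurve(np.tile(conc, 3), y).fit()
            if fit.converged and abs(fit.logec50 + 8.0) < 0.15:
                hits += 1
        assert hits / n_rep >= 0.95


class TestOperationalModel:
    def test_noise_free_partial_agonist_recovery(self, noise_free_design):
        truth = TruthRecord("x", "gprotein", tau=1.0, ka=1e-8)
        panel = gen_conc_response(truth, noise_free_design)
        res = OperationalModel.from_panel(panel, 100.0).fit()
        assert res.converged and not res.full_agonist
        assert res.log_r == pytest.approx(8.0, abs=1e-4)

    def test_full_agonist_limit_logr_is_minus_log_ec50(self, noise_free_design):
        truth = TruthRecord("x", "gprotein", tau=100.0, ka=1e-7)  # EC50_obs ~ 1e-9
        panel = gen_conc_response(truth, noise_free_design)
        res = OperationalModel.from_panel(panel, 100.0).fit()
        assert res.full_agonist
        assert "not separately identifiable" in res.identifiability_note
        assert res.log_r == pytest.approx(9.0, abs=1e-3)

    @pytest.mark.parametrize("tau,ka", [(0.5, 1e-9), (2.0, 3e-8), (50.0, 1e-7)])
    def test_composite_fit_equals_closed_form(self, noise_free_design, tau, ka):
        truth = TruthRecord("x", "gprotein", tau=tau, ka=ka)
        panel = gen_conc_response(truth, noise_free_design)
        op = OperationalModel.from_panel(panel, 100.0).fit()
        lf = LogisticCurve.from_panel(panel).fit()
        closed = logistic_to_logR(lf.top, lf.ec50, 100.0)
        assert op.log_r == pytest.approx(closed, abs=1e-3)

    @pytest.mark.parametrize("tau,ka", [(0.5, 1e-9), (2.0, 3e-8)])
    def test_parameterizations_agree(self, noise_free_design, tau, ka):
        truth = TruthRecord("x", "gprotein", tau=tau, ka=ka)
        panel = gen_conc_response(truth, noise_free_design)
        comp = OperationalModel.from_panel(panel, 100.0,
                                           parameterization="composite").fit()
        joint = OperationalModel.from_panel(panel, 100.0,
                                            parameterization="tau_ka").fit()
        assert comp.log_r == pytest.approx(joint.log_r, abs=1e-6)

    def test_logr_invariant_to_common_response_scaling(self, noise_free_design):
        truth = TruthRecord("x", "gprotein", tau=1.5, ka=1e-8)
        panel = gen_conc_response(truth, noise_free_design)
        res1 = OperationalModel.from_panel(panel, 100.0).fit()
        scaled = panel.data.copy()
        scaled["response"] *= 2.5
        panel2 = ConcResponsePanel("x", "REC", "gprotein", scaled)
        res2 = OperationalModel.from_panel(panel2, 250.0).fit()
        assert res1.log_r == pytest.approx(res2.log_r, abs=1e-6)

    def test_recovery_bias_small_at_design_defaults(self, reference_truth):
        # mean logR error < 0.05 over repeated noisy single-curve fits
        errors = []
        for seed in range(200):
            design = AssayDesign(concentrations=BIAS_PANEL_CONCENTRATIONS.copy(),
                                 n_experiments=1, seed=seed)
            truth = TruthRecord("x", "gprotein", tau=2.0, ka=1e-8)
            panel = gen_conc_response(truth, design)
            res = OperationalModel.from_panel(panel, 100.0).fit()
            if res.converged:
                errors.append(res.log_r - truth.log_r)
        assert len(errors) > 190
        assert abs(np.mean(errors)) < 0.05


class TestNormalization:
    def _noisefree_panel(self, tau, ka, scale=1.0, ligand="REF"):
        conc = BIAS_PANEL_CONCENTRATIONS
        resp = operational_response(conc, 100.0, tau, ka) * scale
        return make_panel(conc, resp, ligand=ligand)

    def test_reference_self_normalizes_to_top_100(self):
        ref = self._noisefree_panel(100.0, 1e-7)
        norm = normalize_to_reference(ref, ref)
        fit = LogisticCurve.from_panel(norm).fit()
        assert fit.top == pytest.approx(100.0, abs=1e-6)

    def test_all_zero_panel_stays_zero(self):
        ref = self._noisefree_panel(100.0, 1e-7)
        zero = make_panel(BIAS_PANEL_CONCENTRATIONS,
                          np.zeros(len(BIAS_PANEL_CONCENTRATIONS)), ligand="z")
        norm = normalize_to_reference(zero, ref)
        np.testing.assert_allclose(norm.data["response"], 0.0, atol=1e-6)

    def test_scale_invariance(self):
        ref = self._noisefree_panel(100.0, 1e-7)
        test = self._noisefree_panel(1.0, 1e-8, ligand="t")
        ref_scaled = self._noisefree_panel(100.0, 1e-7, scale=2.5)
        test_scaled = self._noisefree_panel(1.0, 1e-8, scale=2.5, ligand="t")
        a = normalize_to_reference(test, ref)
        b = normalize_to_reference(test_scaled, ref_scaled)
        np.testing.assert_allclose(a.data["response"], b.data["response"], atol=1e-6)


class TestBretRatio:
    def test_equal_counts_ratio_one(self):
        ratio, flags = bret_ratio([100.0], [100.0])
        assert ratio[0] == 1.0 and not flags[0]

    def test_acceptor_over_donor(self):
        ratio, _ = bret_ratio([510.0], [485.0])
        assert ratio[0] == pytest.approx(510.0 / 485.0)

    def test_vehicle_subtraction_of_identical_wells_is_zero(self):
        ratio, _ = bret_ratio([1.05, 1.05], [1.0, 1.0], vehicle_ratio=[1.05, 1.05])
        np.testing.assert_allclose(ratio, 0.0, atol=1e-12)

    def test_zero_donor_flagged_and_excluded(self):
        ratio, flags = bret_ratio([100.0, 100.0], [0.0, 50.0])
        assert flags[0] and not flags[1]
        assert np.isnan(ratio[0]) and np.isfinite(ratio[1])


class TestLowSignalCheck:
    def test_flat_panel_too_low(self):
        p = make_panel(BIAS_PANEL_CONCENTRATIONS,
                       np.zeros(len(BIAS_PANEL_CONCENTRATIONS)))
        assert low_signal_check(p).too_low

    def test_reference_panel_passes(self):
        conc = BIAS_PANEL_CONCENTRATIONS
        p = make_panel(conc, operational_response(conc, 100.0, 100.0, 1e-7))
        assert not low_signal_check(p, noise_sd=5.0).too_low

    def test_small_span_fails_span_rule(self):
        conc = BIAS_PANEL_CONCENTRATIONS
        p = make_panel(conc, 0.08 * operational_response(conc, 100.0, 100.0, 1e-7))
        v = low_signal_check(p, noise_sd=5.0)
        assert v.too_low and v.span < 10.0

    def test_moderate_span_fails_snr_rule(self):
        conc = BIAS_PANEL_CONCENTRATIONS
        p = make_panel(conc, 0.13 * operational_response(conc, 100.0, 100.0, 1e-5))
        v = low_signal_check(p, noise_sd=5.0)
        assert v.span > 10.0 and v.snr < 3.0 and v.too_low


class TestBiphasicMasking:
    def test_upturn_points_masked(self):
        conc = 10.0 ** np.linspace(-10, -5.5, 10)
        y = logistic3(np.log10(conc), 0.0, 50.0, -8.5)
        y[-2:] += [20.0, 40.0]  # second signalling wave at the top
        panel = make_panel(np.tile(conc, 3), np.tile(y, 3))
        masked_panel, masked = mask_biphasic(panel)
        assert len(masked) == 2
        fit = LogisticCurve.from_panel(masked_panel).fit()
        assert fit.top == pytest.approx(50.0, abs=1.0)

    def test_monophasic_panel_untouched(self):
        conc = 10.0 ** np.linspace(-10, -6, 9)
        y = logistic3(np.log10(conc), 0.0, 100.0, -8.0)
        panel = make_panel(conc, y)
        masked_panel, masked = mask_biphasic(panel)
        assert masked == []
        assert len(masked_panel.data) == len(panel.data)


@given(st.floats(0.1, 1e4), st.floats(1e-10, 1e-6), st.floats(1e-11, 1e-5))
def test_operational_model_is_logistic_with_mapped_parameters(tau, ka, conc):
    """n=1 operational curve == logistic with Emax_obs=Em*tau/(1+tau),
    EC50_obs=K_A/(1+tau)."""
    em = 100.0
    direct = operational_response(conc, em, tau, ka)
    emax_obs = em * tau / (1 + tau)
    ec50_obs = ka / (1 + tau)
    mapped = logistic3(np.log10(conc), 0.0, emax_obs, np.log10(ec50_obs))
    assert direct == pytest.approx(mapped, rel=1e-9)
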