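"""Aldosterone secretagogue model, MR activation, and the reduced
RAAS/electrolyte system (fixed point, response directions, conservation)."""

import numpy as np
import pytest

from pseudoaldo import (DoseRegimen, aldo_steady_state, aldosterone_rhs,
                        build_electrolyte_system, integrate, mr_activation,
                        simulate_cascade)
from pseudoaldo.params import ParameterError
from pseudoaldo.raas import electrolyte_initial_state


class TestAldosterone:
    def test_steady_state_at_normokalemic_baseline(self, raas_params):
        """At K 3.7 mmol/l and AngII 54.4 pg/ml the closed-form steady state
        (~15.6 ng/dl) brackets the observed baselines 13.1 and 21.5."""
        ss = aldo_steady_state(3.7, 54.4, raas_params)
        assert ss == pytest.approx(15.6, rel=0.02)
        assert 13.1 < ss < 21.5

    def test_steady_state_under_suppression(self, raas_params):
        """K 3.3 / AngII 32.4 gives ~6 ng/dl, close to the predicted 5.8."""
        ss = aldo_steady_state(3.3, 32.4, raas_params)
        assert ss == pytest.approx(5.8, rel=0.10)

    def test_no_stimulation_floor(self, raas_params):
        assert aldo_steady_state(0.0, 0.0, raas_params) == pytest.approx(
            62.8 / 18.67, rel=1e-9)

    def test_rhs_zero_at_steady_state(self, raas_params):
        ss = aldo_steady_state(4.0, 50.0, raas_params)
        assert aldosterone_rhs(ss, 4.0, 50.0, raas_params) == pytest.approx(0.0, abs=1e-9)

    def test_negative_secretagogue_rejected(self, raas_params):
        with pytest.raises(ParameterError):
            aldosterone_rhs(10.0, -1.0, 50.0, raas_params)


class TestMrActivation:
    def test_baseline_normalization(self):
        assert mr_activation(15.0, 150.0, Aldo0=15.0, F_k0=150.0) == pytest.approx(1.0)

    def test_monotone_in_cortisol(self):
        a = mr_activation(15.0, 150.0, Aldo0=15.0, F_k0=150.0, gamma=3.0)
        b = mr_activation(15.0, 300.0, Aldo0=15.0, F_k0=150.0, gamma=3.0)
        assert b > a

    def test_compensation_point(self):
        """With the linear transduction (gamma=1), suppressing aldosterone by
        exactly beta*(dF_k/F_k0)*Aldo0 cancels a cortisol rise."""
        beta, Aldo0, Fk0 = 3.0, 15.0, 150.0
        dF = 30.0
        aldo = Aldo0 * (1.0 - beta * dF / Fk0)
        ald = mr_activation(aldo, Fk0 + dF, Aldo0=Aldo0, F_k0=Fk0, beta=beta, gamma=1.0)
        assert ald == pytest.approx(1.0, rel=1e-12)

    def test_low_hsd2_subject_responds_more_at_equal_cortisol_increment(self):
        """Convex transduction: the same absolute kidney-cortisol increment
        produces a larger MR signal in a subject with a higher baseline."""
        ref = 150.0
        dF = 50.0
        normal = mr_activation(15.0, 150.0 + dF, Aldo0=15.0, F_k0=150.0,
                               gamma=3.0, F_k0_ref=ref)
        elderly = mr_activation(15.0, 205.6 + dF, Aldo0=15.0, F_k0=205.6,
                                gamma=3.0, F_k0_ref=ref)
        assert elderly > normal

    def test_zero_baseline_rejected(self):
        with pytest.raises(ParameterError):
            mr_activation(10.0, 100.0, Aldo0=0.0, F_k0=150.0)


class TestElectrolyteSystem:
    def test_global_no_drug_fixed_point_28_days(self, raas_params, electrolyte_params):
        system = build_electrolyte_system(raas_params, electrolyte_params)
        y0 = electrolyte_initial_state(raas_params, electrolyte_params)
        tc = integrate(system, (0.0, 672.0), 0.02, y0, save_every=200)
        for k in ("Aldo", "AngII", "K_ecf", "Na_ecf", "V_ecf", "K_ic"):
            drift = np.max(np.abs(tc[k] / tc[k][0] - 1.0))
            assert drift < 1e-3, k

    def test_sustained_mr_activation_directions(self, raas_params, electrolyte_params):
        """A sustained MR signal elevation lowers serum K monotonically toward
        a plateau, retains sodium, and suppresses renin/AngII and aldosterone."""
        system = build_electrolyte_system(raas_params, electrolyte_params,
                                          ald_fn=lambda t: 3.0)
        y0 = electrolyte_initial_state(raas_params, electrolyte_params)
        tc = integrate(system, (0.0, 28 * 24.0), 0.02, y0, save_every=100)
        K = tc["K_ecf"] / tc["V_ecf"]
        Na = tc["Na_ecf"] / tc["V_ecf"]
        assert np.all(np.diff(K) < 1e-9)
        assert K[-1] < K[0] - 0.1
        # approaching a plateau: the fall decelerates to <10% of its peak rate
        rates = -np.diff(K)
        assert rates[-1] < 0.1 * rates.max()
        assert Na[-1] > Na[0]
        assert Na[-1] < Na[0] + 5.0             # a few mmol/l at most
        assert tc["AngII"][-1] < tc["AngII"][0]
        assert tc["Aldo"][-1] < tc["Aldo"][0]   # compensatory RAAS suppression

    def test_potassium_conservation(self, raas_params, electrolyte_params):
        """Intake - urinary excretion - change of body pools = 0."""
        system = build_electrolyte_system(raas_params, electrolyte_params,
                                          ald_fn=lambda t: 1.3)
        y0 = electrolyte_initial_state(raas_params, electrolyte_params)
        tc = integrate(system, (0.0, 240.0), 0.02, y0, save_every=100)
        intake = electrolyte_params.K_intake * 240.0
        excreted = tc["U_K"][-1]
        dpools = (tc["K_ecf"][-1] - tc["K_ecf"][0]) + (tc["K_ic"][-1] - tc["K_ic"][0])
        assert intake - excreted - dpools == pytest.approx(0.0, abs=5e-3 * intake)


class TestCascadeCompensation:
    def test_raas_suppressed_below_baseline_under_sustained_dosing(
            self, human_config, hsd2_params, raas_params, ga500_regimen):
        from pseudoaldo import default_electrolyte_params
        ep = default_electrolyte_params(K_serum0=3.7, Na_serum0=141.0, AngII0=54.4)
        tc = simulate_cascade(human_config, ga500_regimen, hsd2_params,
                              raas_params, ep, Aldo_init=13.1, step=0.02)
        assert tc["Aldo"][-1] < 13.1
        assert tc["AngII"][-1] < 54.4
        assert np.all(tc["K_serum"][1:] > 1.5) and np.all(tc["K_serum"] < 8.0)
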