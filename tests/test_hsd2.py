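"""11beta-HSD2 module: inhibition law, baseline closure, step response,
reversibility and the urinary cortisol:cortisone ratio."""

import numpy as np
import pytest

from pseudoaldo import (derive_baseline_params, inhibited_kox,
                        simulate_cortisol_cortisone, urinary_ratio_24h)
from pseudoaldo.hsd2 import with_kox0
from pseudoaldo.ode import TimeCourse
from pseudoaldo.params import ParameterError


def flat_exposure(level_umol_l, t_end=240.0):
    ts = np.array([0.0, t_end])
    return TimeCourse(times=ts, series={"C_kidney_GA": np.full(2, level_umol_l)})


class TestInhibitedKox:
    def test_no_drug_gives_baseline(self, hsd2_params):
        assert inhibited_kox(0.0, hsd2_params) == hsd2_params.k_ox0

    def test_ic50_halves_clearance(self, hsd2_params):
        assert inhibited_kox(0.000234, hsd2_params) == pytest.approx(
            hsd2_params.k_ox0 / 2)

    def test_full_inhibition_limit(self, hsd2_params):
        assert inhibited_kox(1e6, hsd2_params) == pytest.approx(0.0, abs=1e-9)

    def test_negative_concentration_rejected(self, hsd2_params):
        with pytest.raises(ParameterError):
            inhibited_kox(-0.1, hsd2_params)


class TestBaselineDerivation:
    def test_drug_free_system_is_exact_fixed_point(self, hsd2_params):
        tc = simulate_cortisol_cortisone(flat_exposure(0.0), hsd2_params,
                                         step=0.02)
        assert np.allclose(tc["F_k"], hsd2_params.F_k0, rtol=1e-12)
        assert np.allclose(tc["E"], hsd2_params.E_0, rtol=1e-12)

    def test_baseline_urinary_ratio_identity(self, hsd2_params):
        p = hsd2_params
        assert p.baseline_urinary_ratio == pytest.approx(
            p.urinary_cortisol_24h / p.urinary_cortisone_24h)
        assert p.baseline_urinary_ratio == pytest.approx(0.65)

    def test_normal_kox0_about_1p8_fold_elderly(self, hsd2_params):
        assert hsd2_params.k_ox0 / 0.02 == pytest.approx(1.8, rel=0.02)

    def test_low_hsd2_subject_has_higher_kidney_cortisol(self, hsd2_params):
        eld = with_kox0(hsd2_params, 0.02)
        assert eld.F_k0 > hsd2_params.F_k0
        # plasma cortisol:cortisone ratio is higher in the low-HSD2 subject
        assert eld.F_0 / eld.E_0 > hsd2_params.F_0 / hsd2_params.E_0
        # production and urinary clearances are population properties
        assert eld.k_0 == hsd2_params.k_0
        assert eld.k_ur_E == hsd2_params.k_ur_E

    def test_inconsistent_baseline_rejected(self):
        with pytest.raises(ParameterError):
            derive_baseline_params(F_0=-1.0, E_0=17.0, K_tp_cortisol=1.5,
                                   urinary_cortisol_24h=84.5,
                                   urinary_cortisone_24h=130.0)


class TestDynamics:
    def test_step_response_approaches_closed_form_ceiling(self, hsd2_params):
        """At saturating GA the oxidation stops: F_k -> k_0/k_ur_F and the
        cortisone formation rate -> 0."""
        p = hsd2_params
        tc = simulate_cortisol_cortisone(flat_exposure(1e4), p, step=0.02)
        ceiling = p.k_0 / p.k_ur_F
        assert tc["F_k"][-1] == pytest.approx(ceiling, rel=1e-3)
        assert tc["E"][-1] < 0.05 * p.E_0

    def test_washout_reversibility(self, hsd2_params):
        """After >= 5 slowest time constants of washout the states return to
        within 1% of baseline (reversible inhibition)."""
        p = hsd2_params
        ts = np.array([0.0, 120.0, 120.01, 600.0])
        cs = np.array([2e-3, 2e-3, 0.0, 0.0])  # strong exposure, then washout
        tc = simulate_cortisol_cortisone(
            TimeCourse(times=ts, series={"C_kidney_GA": cs}), p, step=0.02)
        assert abs(tc["F_k"][-1] / p.F_k0 - 1) < 0.01
        assert abs(tc["E"][-1] / p.E_0 - 1) < 0.01

    def test_cortisol_mass_balance(self, hsd2_params):
        """k_0*t = delta(F_k*V_k) + integral(k_ox*F_k) + integral(k_ur_F*F_k)."""
        p = hsd2_params
        tc = simulate_cortisol_cortisone(flat_exposure(5e-4, 96.0), p, step=0.01)
        t = tc.times
        ic50 = p.IC50 * 1000.0
        kox = p.k_ox0 * (1 - 5e-4 / (ic50 + 5e-4))
        produced = p.k_0 * t[-1]
        stored = (tc["F_k"][-1] - p.F_k0) * p.V_k
        oxidized = np.trapezoid(kox * tc["F_k"], t)
        excreted = tc["U_F"][-1]
        assert produced == pytest.approx(stored + oxidized + excreted, rel=5e-3)


class TestUrinaryRatio:
    def test_no_drug_ratio_is_baseline(self, hsd2_params):
        tc = simulate_cortisol_cortisone(flat_exposure(0.0, 48.0), hsd2_params,
                                         step=0.02)
        assert urinary_ratio_24h(tc, 1) == pytest.approx(0.65, rel=1e-9)

    def test_ratio_monotone_in_exposure(self, hsd2_params):
        ratios = [urinary_ratio_24h(
            simulate_cortisol_cortisone(flat_exposure(c, 48.0), hsd2_params,
                                        step=0.02), 2)
            for c in (0.0, 1e-4, 3e-4, 1e-3)]
        assert np.all(np.diff(ratios) > 0)

    def test_scaling_both_urinary_clearances_leaves_ratio(self, hsd2_params):
        """R = (k_ur_F*F_k)/(k_ur_E*E): a common factor on both urinary
        clearances cancels at fixed concentrations."""
        from dataclasses import replace
        p = hsd2_params
        p2 = replace(p, k_ur_F=2 * p.k_ur_F, k_ur_E=2 * p.k_ur_E)
        r1 = (p.k_ur_F * p.F_k0) / (p.k_ur_E * p.E_0)
        r2 = (p2.k_ur_F * p2.F_k0) / (p2.k_ur_E * p2.E_0)
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_day_outside_span_rejected(self, hsd2_params):
        tc = simulate_cortisol_cortisone(flat_exposure(0.0, 24.0), hsd2_params,
                                         step=0.05)
        with pytest.raises(ValueError):
            urinary_ratio_24h(tc, 3)
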