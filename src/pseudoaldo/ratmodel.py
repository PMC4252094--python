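"""Rat semi-PBPK model for glycyrrhizin (GL), glycyrrhetic acid (GA) and the
pooled phase-II conjugates (GAM, including 3-monoglucuronyl-GA).

Structure: a central distribution pool (vascular plasma in flow equilibrium
with the perfusion-limited kidney and gut tissue and with the hepatic
sinusoidal/venous sub-compartment), a lumped remaining tissue, a split liver
(saturable sinusoidal uptake from the venous sub-compartment, first-order
sinusoidal efflux and metabolic clearance on unbound liver-tissue
concentration, saturable biliary excretion for GL and GAM), a bile-duct
transit delay discharging into the duodenum (or a fistula sink), and a
six-segment gut lumen transit chain with microbial hydrolysis of GL (cecum +
colon) and GAM (both segments) to GA and GA absorption into the portal
stream. Renal clearance is ignored for all three species, oral GL is not
absorbed, and drug is confined to plasma (flows are scaled by 1-hematocrit).

The kidney, gut tissue and sinusoid have residence times of seconds relative
to every kinetic process in the model, so their amounts track plasma
equilibrium algebraically; they are included in the reported series and in
the molar mass balance. All quantities: ml, umol, h.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .ode import OdeSystem, TimeCourse, integrate, schedule_events
from .params import DoseRegimen, ModelConfig, ParameterError, load_parameters

# --- state indices -----------------------------------------------------------
# per-compound blocks, then cumulative sinks
GL_X, GL_AL, GL_AR, GL_AB, GL_DEP, GL_ST, GL_SA, GL_SB, GL_SC, GL_CE, GL_CO = range(11)
(GA_X, GA_AL, GA_AR, GA_DEP, GA_ST, GA_SA, GA_SB, GA_SC, GA_CE, GA_CO) = range(11, 21)
GAM_AL, GAM_AB, GAM_SA, GAM_SB, GAM_SC, GAM_CE, GAM_CO = range(21, 28)
FEC_GL, FEC_GA, FEC_GAM, FIST_GL, FIST_GAM, ABS_GA, BILE_GL, BILE_GAM = range(28, 36)
N_STATES = 36

STATE_NAMES = [
    "GL_central", "GL_liver", "GL_remaining", "GL_bile", "GL_depot",
    "GL_lumen_st", "GL_lumen_sa", "GL_lumen_sb", "GL_lumen_sc", "GL_lumen_ce", "GL_lumen_co",
    "GA_central", "GA_liver", "GA_remaining", "GA_depot",
    "GA_lumen_st", "GA_lumen_sa", "GA_lumen_sb", "GA_lumen_sc", "GA_lumen_ce", "GA_lumen_co",
    "GAM_liver", "GAM_bile",
    "GAM_lumen_sa", "GAM_lumen_sb", "GAM_lumen_sc", "GAM_lumen_ce", "GAM_lumen_co",
    "fecal_GL", "fecal_GA", "fecal_GAM", "fistula_GL", "fistula_GAM",
    "absorbed_GA", "cum_biliary_GL", "cum_biliary_GAM",
]

# --- parameter indices -------------------------------------------------------
P_VPL, P_VL, P_VVL, P_Q, P_KST, P_KSA, P_KSB, P_KSC, P_KCE, P_KCO, P_KBILE, P_KIP, P_FIST = range(13)
# per-compound blocks at offsets 20 (GL), 40 (GA), 60 (GAM)
C_VEFF, C_FU, C_FUT, C_K12, C_K21, C_VMAX, C_KM, C_VMAXB, C_KMB, C_CLMET, C_PSEFF, \
    C_KABSSI, C_KABSCO, C_KHCE, C_KHCO, C_PK = range(16)
OFF = {"GL": 20, "GA": 40, "GAM": 60}
N_PARAMS = 80


@njit(cache=True, fastmath=True, inline="always")
def _sinusoid(Q, fu, Vmax, Km, C, S):
    """Sinusoidal (liver-venous) plasma concentration under flow equilibrium.

    Solves Q*x + Vmax*fu*x/(Km + fu*x) = Q*C + S for x >= 0 (quadratic).
    """
    B = Q * C + S
    if B <= 0.0:
        return 0.0
    if Vmax <= 0.0 or fu <= 0.0:
        return B / Q
    b = Q * Km + fu * (Vmax - B)
    disc = b * b + 4.0 * Q * fu * Km * B
    return (-b + math.sqrt(disc)) / (2.0 * Q * fu)


@njit(cache=True, fastmath=True, inline="always")
def _central_conc(X, S, Veff, Vvl, Q, fu, Vmax, Km):
    """Invert X = Veff*C + Vvl*Cvl(C) for the plasma concentration C."""
    if X <= 0.0 and S <= 0.0:
        return 0.0, 0.0
    C = X / (Veff + Vvl)
    if C < 0.0:
        C = 0.0
    Cvl = 0.0
    for _ in range(3):
        Cvl = _sinusoid(Q, fu, Vmax, Km, C, S)
        C = (X - Vvl * Cvl) / Veff
        if C < 0.0:
            C = 0.0
    return C, Cvl


@njit(cache=True, fastmath=True)
def rat_rhs(t, y, p, out):  # noqa: C901 - one flat kernel keeps the batch loop fast
    m = y.shape[0]
    for i in range(m):
        Vpl = p[i, P_VPL]; Vl = p[i, P_VL]; Vvl = p[i, P_VVL]; Q = p[i, P_Q]
        kst = p[i, P_KST]; ksa = p[i, P_KSA]; ksb = p[i, P_KSB]; ksc = p[i, P_KSC]
        kce = p[i, P_KCE]; kco = p[i, P_KCO]
        kbile = p[i, P_KBILE]; kip = p[i, P_KIP]; fist = p[i, P_FIST]

        # ---- GL -------------------------------------------------------
        o = 20
        Cl_gl = y[i, GL_AL] / Vl
        Cul_gl = p[i, o + C_FUT] * Cl_gl
        eff_gl = p[i, o + C_PSEFF] * Cul_gl
        S_gl = eff_gl + kip * y[i, GL_DEP]          # no oral GL absorption
        C_gl, Cvl_gl = _central_conc(
            y[i, GL_X], S_gl, p[i, o + C_VEFF], Vvl, Q,
            p[i, o + C_FU], p[i, o + C_VMAX], p[i, o + C_KM])
        fuC = p[i, o + C_FU] * Cvl_gl
        upt_gl = p[i, o + C_VMAX] * fuC / (p[i, o + C_KM] + fuC) if fuC > 0 else 0.0
        met_gl = p[i, o + C_CLMET] * Cul_gl
        bil_gl = p[i, o + C_VMAXB] * Cul_gl / (p[i, o + C_KMB] + Cul_gl) if Cul_gl > 0 else 0.0
        out[i, GL_X] = S_gl + p[i, o + C_K21] * y[i, GL_AR] - upt_gl - p[i, o + C_K12] * C_gl
        out[i, GL_AL] = upt_gl - eff_gl - met_gl - bil_gl
        out[i, GL_AR] = p[i, o + C_K12] * C_gl - p[i, o + C_K21] * y[i, GL_AR]
        out[i, GL_AB] = bil_gl - kbile * y[i, GL_AB]
        out[i, GL_DEP] = -kip * y[i, GL_DEP]
        bile_out_gl = kbile * y[i, GL_AB]
        khce_gl = p[i, o + C_KHCE]; khco_gl = p[i, o + C_KHCO]
        out[i, GL_ST] = -kst * y[i, GL_ST]
        out[i, GL_SA] = kst * y[i, GL_ST] - ksa * y[i, GL_SA] + (0.0 if fist > 0.5 else bile_out_gl)
        out[i, GL_SB] = ksa * y[i, GL_SA] - ksb * y[i, GL_SB]
        out[i, GL_SC] = ksb * y[i, GL_SB] - ksc * y[i, GL_SC]
        out[i, GL_CE] = ksc * y[i, GL_SC] - (kce + khce_gl) * y[i, GL_CE]
        out[i, GL_CO] = kce * y[i, GL_CE] - (kco + khco_gl) * y[i, GL_CO]

        # ---- GAM ------------------------------------------------------
        o = 60
        Cul_gam = p[i, o + C_FUT] * (y[i, GAM_AL] / Vl)
        bil_gam = p[i, o + C_VMAXB] * Cul_gam / (p[i, o + C_KMB] + Cul_gam) if Cul_gam > 0 else 0.0
        bile_out_gam = kbile * y[i, GAM_AB]
        khce_gam = p[i, o + C_KHCE]; khco_gam = p[i, o + C_KHCO]
        out[i, GAM_AB] = bil_gam - bile_out_gam
        out[i, GAM_SA] = (0.0 if fist > 0.5 else bile_out_gam) - ksa * y[i, GAM_SA]
        out[i, GAM_SB] = ksa * y[i, GAM_SA] - ksb * y[i, GAM_SB]
        out[i, GAM_SC] = ksb * y[i, GAM_SB] - ksc * y[i, GAM_SC]
        out[i, GAM_CE] = ksc * y[i, GAM_SC] - (kce + khce_gam) * y[i, GAM_CE]
        out[i, GAM_CO] = kce * y[i, GAM_CE] - (kco + khco_gam) * y[i, GAM_CO]

        # ---- GA -------------------------------------------------------
        o = 40
        kabs_si = p[i, o + C_KABSSI]; kabs_co = p[i, o + C_KABSCO]
        J_abs = (kabs_si * (y[i, GA_SA] + y[i, GA_SB] + y[i, GA_SC])
                 + kabs_co * (y[i, GA_CE] + y[i, GA_CO]))
        Cl_ga = y[i, GA_AL] / Vl
        Cul_ga = p[i, o + C_FUT] * Cl_ga
        eff_ga = p[i, o + C_PSEFF] * Cul_ga
        S_ga = eff_ga + J_abs + kip * y[i, GA_DEP]
        C_ga, Cvl_ga = _central_conc(
            y[i, GA_X], S_ga, p[i, o + C_VEFF], Vvl, Q,
            p[i, o + C_FU], p[i, o + C_VMAX], p[i, o + C_KM])
        fuC = p[i, o + C_FU] * Cvl_ga
        upt_ga = p[i, o + C_VMAX] * fuC / (p[i, o + C_KM] + fuC) if fuC > 0 else 0.0
        met_ga = p[i, o + C_CLMET] * Cul_ga
        out[i, GA_X] = S_ga + p[i, o + C_K21] * y[i, GA_AR] - upt_ga - p[i, o + C_K12] * C_ga
        out[i, GA_AL] = upt_ga - eff_ga - met_ga
        out[i, GA_AR] = p[i, o + C_K12] * C_ga - p[i, o + C_K21] * y[i, GA_AR]
        out[i, GA_DEP] = -kip * y[i, GA_DEP]
        out[i, GA_ST] = -kst * y[i, GA_ST]
        out[i, GA_SA] = kst * y[i, GA_ST] - (ksa + kabs_si) * y[i, GA_SA]
        out[i, GA_SB] = ksa * y[i, GA_SA] - (ksb + kabs_si) * y[i, GA_SB]
        out[i, GA_SC] = ksb * y[i, GA_SB] - (ksc + kabs_si) * y[i, GA_SC]
        out[i, GA_CE] = (ksc * y[i, GA_SC] - (kce + kabs_co) * y[i, GA_CE]
                         + khce_gl * y[i, GL_CE] + khce_gam * y[i, GAM_CE])
        out[i, GA_CO] = (kce * y[i, GA_CE] - (kco + kabs_co) * y[i, GA_CO]
                         + khco_gl * y[i, GL_CO] + khco_gam * y[i, GAM_CO])

        out[i, GAM_AL] = met_gl + met_ga - bil_gam

        # ---- sinks ----------------------------------------------------
        out[i, FEC_GL] = kco * y[i, GL_CO]
        out[i, FEC_GA] = kco * y[i, GA_CO]
        out[i, FEC_GAM] = kco * y[i, GAM_CO]
        out[i, FIST_GL] = bile_out_gl if fist > 0.5 else 0.0
        out[i, FIST_GAM] = bile_out_gam if fist > 0.5 else 0.0
        out[i, ABS_GA] = J_abs
        out[i, BILE_GL] = bil_gl
        out[i, BILE_GAM] = bil_gam


def pack_rat_params(config: ModelConfig, fistula: bool = False) -> np.ndarray:
    """Pack a rat configuration into the compiled-RHS parameter row."""
    if config.species != "rat":
        raise ParameterError("rat model requires a rat parameter set")
    phys = config.physiology
    hct = config.compound("GL").hematocrit
    p = np.zeros(N_PARAMS)
    p[P_VPL] = phys.volumes["vascular"] * (1 - hct)
    p[P_VL] = phys.volumes["liver"]
    p[P_VVL] = phys.volumes["liver_venous"] * (1 - hct)
    p[P_Q] = phys.liver_blood_flow * (1 - hct)
    for idx, key in zip((P_KST, P_KSA, P_KSB, P_KSC, P_KCE, P_KCO),
                        ("K_st", "K_sa", "K_sb", "K_sc", "K_ce", "K_co")):
        p[idx] = phys.transit[key]
    p[P_KBILE] = phys.bile_transit
    p[P_KIP] = phys.ip_absorption
    p[P_FIST] = 1.0 if fistula else 0.0
    for name in ("GL", "GA", "GAM"):
        cp = config.compound(name).model_values()
        o = OFF[name]
        p[o + C_VEFF] = (p[P_VPL] + cp["P_k"] * phys.volumes["kidneys"]
                         + cp["P_g"] * phys.volumes["guts"])
        p[o + C_FU] = cp["f_u"]
        p[o + C_FUT] = cp["f_ut"]
        p[o + C_K12] = cp["K_12_r"]
        p[o + C_K21] = cp["K_21_r"]
        p[o + C_VMAX] = cp["V_max"]
        p[o + C_KM] = cp["K_m"]
        p[o + C_VMAXB] = cp["V_max_B"]
        p[o + C_KMB] = cp["K_m_B"]
        p[o + C_CLMET] = cp["CL_met"]
        p[o + C_PSEFF] = cp["PS_eff"]
        p[o + C_KABSSI] = cp["K_abs_si"]
        p[o + C_KABSCO] = cp["K_abs_co"]
        p[o + C_KHCE] = cp["KH_ce"]
        p[o + C_KHCO] = cp["KH_co"]
        p[o + C_PK] = cp["P_k"]
    return p


_DOSE_LAYOUT = {
    "GL": {"central": GL_X, "stomach": GL_ST, "depot": GL_DEP},
    "GA": {"central": GA_X, "stomach": GA_ST, "depot": GA_DEP},
    # GAM has no printed systemic/absorption parameters; dosing it is rejected
    "GAM": {},
}


def build_rat_system(config: ModelConfig, regimen: DoseRegimen,
                     t_end: float | None = None) -> OdeSystem:
    """Assemble the rat ODE system with the regimen's dose events."""
    for name in ("GL", "GA", "GAM"):
        config.compound(name)  # raises a build error when absent
    t_end = t_end if t_end is not None else 24.0 * regimen.n_days
    p = pack_rat_params(config, fistula=regimen.bile_fistula)
    mw = config.compound(regimen.compound).molecular_weight
    dose = regimen.dose_umol(mw, config.physiology.body_weight)
    events = schedule_events(regimen, _DOSE_LAYOUT[regimen.compound], dose, t_end)
    return OdeSystem(state_names=STATE_NAMES, rhs=rat_rhs, events=events,
                     params=p[None, :], compiled=True,
                     metadata={"species": "rat", "regimen": regimen, "t_end": t_end})


def _derived_series(p: np.ndarray):
    """Series function adding plasma/kidney concentrations and balance terms."""

    def fn(ts: np.ndarray, states: np.ndarray) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, xi, ali in (("GL", GL_X, GL_AL), ("GA", GA_X, GA_AL)):
            o = OFF[name]
            C = np.empty_like(ts)
            for k in range(ts.size):
                y = states[k]
                if name == "GL":
                    Cul = p[o + C_FUT] * y[GL_AL] / p[P_VL]
                    S = p[o + C_PSEFF] * Cul + p[P_KIP] * y[GL_DEP]
                else:
                    J = (p[o + C_KABSSI] * (y[GA_SA] + y[GA_SB] + y[GA_SC])
                         + p[o + C_KABSCO] * (y[GA_CE] + y[GA_CO]))
                    Cul = p[o + C_FUT] * y[GA_AL] / p[P_VL]
                    S = p[o + C_PSEFF] * Cul + J + p[P_KIP] * y[GA_DEP]
                C[k], _ = _central_conc(y[xi], S, p[o + C_VEFF], p[P_VVL], p[P_Q],
                                        p[o + C_FU], p[o + C_VMAX], p[o + C_KM])
            out[f"C_plasma_{name}"] = C
            out[f"C_kidney_{name}"] = p[o + C_PK] * C
        out["total_umol"] = states.sum(axis=1) - states[:, [ABS_GA, BILE_GL, BILE_GAM]].sum(axis=1)
        return out

    return fn


def simulate_rat(config: ModelConfig, regimen: DoseRegimen, t_end: float | None = None,
                 step: float = 0.01, save_every: int = 10) -> TimeCourse:
    """Simulate a rat regimen; returns plasma/kidney concentrations (umol/ml),
    compartment amounts (umol) and cumulative biliary excretion."""
    system = build_rat_system(config, regimen, t_end)
    y0 = np.zeros(N_STATES)
    tc = integrate(system, (0.0, system.metadata["t_end"]), step, y0,
                   save_every=save_every, series_fn=_derived_series(system.params[0]))
    return tc


def kidney_exposure(tc: TimeCourse, window: tuple[float, float] | None = None,
                    compound: str = "GA") -> dict:
    """Kidney concentration series and trapezoid AUC over ``window``.

    Returns ``{"series": C_k(t), "auc": umol*h/ml, "window": (lo, hi)}``.
    """
    key = f"C_kidney_{compound}"
    if key not in tc.series:
        raise KeyError(f"kidney series {key!r} not present in time course")
    window = window or (float(tc.times[0]), float(tc.times[-1]))
    return {"series": tc.series[key], "auc": tc.auc(key, window), "window": window}


def mass_balance_error(tc: TimeCourse, dosed_umol: float) -> float:
    """Worst relative deviation of total moles (all compounds + sinks) from
    the administered molar dose, over the whole trajectory after first dose."""
    total = tc.series["total_umol"]
    mask = total > 1e-9
    if dosed_umol <= 0:
        return float(np.max(np.abs(total))) if np.any(mask) else 0.0
    return float(np.max(np.abs(total[mask] - dosed_umol))) / dosed_umol


def default_rat_config() -> ModelConfig:
    return load_parameters(species="rat")
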