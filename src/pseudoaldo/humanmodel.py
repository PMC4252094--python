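"""Human PBPK model for GL/GA/GAM and the combined PK->PD cascade.

Topology as the rat model but with a three-segment gut lumen (stomach, small
intestine, colon), linear hepatic sinusoidal uptake (CL_up) and biliary
excretion (CL_b), and gallbladder storage of the biliary output of GL and
GAM that is discharged into the small-intestinal lumen at meal times. GL is
hydrolyzed to GA in the colon (4-fold faster from a whole-licorice matrix),
GAM in the colon; GA is absorbed from the small intestine and colon, GL
(enterohepatic recycling) from the small intestine.

The same compiled right-hand side carries the full pharmacodynamic cascade
(11beta-HSD2 inhibition by kidney GA, MR activation, RAAS/electrolytes), so
one batched integration serves scenario simulation, sensitivity sweeps and
the Monte Carlo virtual population. Units: l, umol, h; PD units as in
:mod:`pseudoaldo.raas`.

Interspecies scaling utilities (allometric clearance scaling, liver-weight
scaling, microsomal-binding correction) live here as derivation tools; the
published human table remains authoritative at run time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .hsd2 import Hsd2Params
from .ode import OdeSystem, TimeCourse, integrate, integrate_batch, schedule_events
from .params import DoseRegimen, ModelConfig, ParameterError, load_parameters
from .raas import ElectrolyteParams, RaasParams, aldo_steady_state

# --- state indices -----------------------------------------------------------
GL_X, GL_AL, GL_AR, GL_GB, GL_ST, GL_SI, GL_CO = range(7)
GA_X, GA_AL, GA_AR, GA_ST, GA_SI, GA_CO = range(7, 13)
GAM_AL, GAM_GB, GAM_SI, GAM_CO = range(13, 17)
FEC_GL, FEC_GA, FEC_GAM, FIST_GL, FIST_GAM, ABS_GL, ABS_GA, BILE_GL, BILE_GAM = range(17, 26)
PD_FK, PD_E, PD_UF, PD_UE, PD_ALDO, PD_PRA, PD_ANG, PD_KEC, PD_KIC, PD_NAEC, PD_VEC, \
    PD_UK, PD_UNA = range(26, 39)
N_STATES = 39

STATE_NAMES = [
    "GL_central", "GL_liver", "GL_remaining", "GL_gallbladder",
    "GL_lumen_st", "GL_lumen_si", "GL_lumen_co",
    "GA_central", "GA_liver", "GA_remaining",
    "GA_lumen_st", "GA_lumen_si", "GA_lumen_co",
    "GAM_liver", "GAM_gallbladder", "GAM_lumen_si", "GAM_lumen_co",
    "fecal_GL", "fecal_GA", "fecal_GAM", "fistula_GL", "fistula_GAM",
    "absorbed_GL", "absorbed_GA", "cum_biliary_GL", "cum_biliary_GAM",
    "F_k", "E", "U_F", "U_E", "Aldo", "PRA", "AngII",
    "K_ecf", "K_ic", "Na_ecf", "V_ecf", "U_K", "U_Na",
]

# --- parameter indices -------------------------------------------------------
P_VPL, P_VL, P_VVL, P_Q, P_KST, P_KS, P_KCO, P_FIST, P_PDON = range(9)
C_VEFF, C_FU, C_FUT, C_K12, C_K21, C_CLUP, C_CLB, C_CLMET, C_PSEFF, \
    C_KABSSI, C_KABSCO, C_KHCO, C_PK = range(13)
OFF = {"GL": 10, "GA": 30, "GAM": 50}
(Q_IC50, Q_KOX0, Q_KURF, Q_KURE, Q_K0C, Q_VKPD, Q_VAPP, Q_FK0, Q_E0) = range(70, 79)
(Q_KGEN, Q_SMAX, Q_SC50K, Q_SC50A, Q_KDEG, Q_RHILL, Q_ALDO0, Q_BETA,
 Q_KS0, Q_NA0, Q_ANGII0, Q_VEC0, Q_AKIC0, Q_IK, Q_INA, Q_KX, Q_KW, Q_HVOL,
 Q_GP, Q_GGFR, Q_GR, Q_KREN, Q_KANG, Q_AGFR, Q_BNA, Q_GALDK, Q_GALDNA,
 Q_BK, Q_GAMMA, Q_FK0REF) = range(80, 110)
N_PARAMS = 110


@njit(cache=True, fastmath=True)
def cascade_rhs(t, y, p, out):  # noqa: C901
    m = y.shape[0]
    for i in range(m):
        Vpl = p[i, P_VPL]; Vl = p[i, P_VL]; Vvl = p[i, P_VVL]; Q = p[i, P_Q]
        kst = p[i, P_KST]; ks = p[i, P_KS]; kco = p[i, P_KCO]
        fist = p[i, P_FIST]

        # ---- GL -------------------------------------------------------
        o = 10
        Cul_gl = p[i, o + C_FUT] * (y[i, GL_AL] / Vl)
        eff_gl = p[i, o + C_PSEFF] * Cul_gl
        J_abs_gl = p[i, o + C_KABSSI] * y[i, GL_SI]
        S_gl = eff_gl + J_abs_gl
        D_gl = Q + p[i, o + C_FU] * p[i, o + C_CLUP]
        C_gl = (y[i, GL_X] - Vvl * S_gl / D_gl) / (p[i, o + C_VEFF] + Vvl * Q / D_gl)
        if C_gl < 0.0:
            C_gl = 0.0
        Cvl_gl = (Q * C_gl + S_gl) / D_gl
        upt_gl = p[i, o + C_FU] * p[i, o + C_CLUP] * Cvl_gl
        met_gl = p[i, o + C_CLMET] * Cul_gl
        bil_gl = p[i, o + C_CLB] * Cul_gl
        khco_gl = p[i, o + C_KHCO]
        out[i, GL_X] = S_gl + p[i, o + C_K21] * y[i, GL_AR] - upt_gl - p[i, o + C_K12] * C_gl
        out[i, GL_AL] = upt_gl - eff_gl - met_gl - bil_gl
        out[i, GL_AR] = p[i, o + C_K12] * C_gl - p[i, o + C_K21] * y[i, GL_AR]
        out[i, GL_GB] = 0.0 if fist > 0.5 else bil_gl
        out[i, GL_ST] = -kst * y[i, GL_ST]
        out[i, GL_SI] = kst * y[i, GL_ST] - (ks + p[i, o + C_KABSSI]) * y[i, GL_SI]
        out[i, GL_CO] = ks * y[i, GL_SI] - (kco + khco_gl) * y[i, GL_CO]

        # ---- GAM ------------------------------------------------------
        o = 50
        Cul_gam = p[i, o + C_FUT] * (y[i, GAM_AL] / Vl)
        bil_gam = p[i, o + C_CLB] * Cul_gam
        khco_gam = p[i, o + C_KHCO]
        out[i, GAM_GB] = 0.0 if fist > 0.5 else bil_gam
        out[i, GAM_SI] = -ks * y[i, GAM_SI]
        out[i, GAM_CO] = ks * y[i, GAM_SI] - (kco + khco_gam) * y[i, GAM_CO]

        # ---- GA -------------------------------------------------------
        o = 30
        kabs_si = p[i, o + C_KABSSI]; kabs_co = p[i, o + C_KABSCO]
        J_abs_ga = kabs_si * y[i, GA_SI] + kabs_co * y[i, GA_CO]
        Cul_ga = p[i, o + C_FUT] * (y[i, GA_AL] / Vl)
        eff_ga = p[i, o + C_PSEFF] * Cul_ga
        S_ga = eff_ga + J_abs_ga
        D_ga = Q + p[i, o + C_FU] * p[i, o + C_CLUP]
        C_ga = (y[i, GA_X] - Vvl * S_ga / D_ga) / (p[i, o + C_VEFF] + Vvl * Q / D_ga)
        if C_ga < 0.0:
            C_ga = 0.0
        Cvl_ga = (Q * C_ga + S_ga) / D_ga
        upt_ga = p[i, o + C_FU] * p[i, o + C_CLUP] * Cvl_ga
        met_ga = p[i, o + C_CLMET] * Cul_ga
        out[i, GA_X] = S_ga + p[i, o + C_K21] * y[i, GA_AR] - upt_ga - p[i, o + C_K12] * C_ga
        out[i, GA_AL] = upt_ga - eff_ga - met_ga
        out[i, GA_AR] = p[i, o + C_K12] * C_ga - p[i, o + C_K21] * y[i, GA_AR]
        out[i, GA_ST] = -kst * y[i, GA_ST]
        out[i, GA_SI] = kst * y[i, GA_ST] - (ks + kabs_si) * y[i, GA_SI]
        out[i, GA_CO] = (ks * y[i, GA_SI] - (kco + kabs_co) * y[i, GA_CO]
                         + khco_gl * y[i, GL_CO] + khco_gam * y[i, GAM_CO])

        out[i, GAM_AL] = met_gl + met_ga - bil_gam

        # ---- sinks ----------------------------------------------------
        out[i, FEC_GL] = kco * y[i, GL_CO]
        out[i, FEC_GA] = kco * y[i, GA_CO]
        out[i, FEC_GAM] = kco * y[i, GAM_CO]
        out[i, FIST_GL] = bil_gl if fist > 0.5 else 0.0
        out[i, FIST_GAM] = bil_gam if fist > 0.5 else 0.0
        out[i, ABS_GL] = J_abs_gl
        out[i, ABS_GA] = J_abs_ga
        out[i, BILE_GL] = bil_gl
        out[i, BILE_GAM] = bil_gam

        # ---- pharmacodynamics ----------------------------------------
        if p[i, P_PDON] > 0.5:
            Ck = p[i, 30 + C_PK] * C_ga          # kidney GA, umol/l
            kox = p[i, Q_KOX0] * (1.0 - Ck / (p[i, Q_IC50] + Ck))
            Fk = y[i, PD_FK]; E = y[i, PD_E]
            out[i, PD_FK] = (p[i, Q_K0C] - (kox + p[i, Q_KURF]) * Fk) / p[i, Q_VKPD]
            out[i, PD_E] = (kox * Fk - p[i, Q_KURE] * E) / p[i, Q_VAPP]
            out[i, PD_UF] = p[i, Q_KURF] * Fk
            out[i, PD_UE] = p[i, Q_KURE] * E

            Aldo = y[i, PD_ALDO]; PRA = y[i, PD_PRA]; Ang = y[i, PD_ANG]
            Kec = y[i, PD_KEC]; Kic = y[i, PD_KIC]; Naec = y[i, PD_NAEC]
            Vec = y[i, PD_VEC]
            Ks_s = Kec / Vec
            Nas = Naec / Vec
            r = p[i, Q_RHILL]
            kr = Ks_s ** r
            s_K = kr / (p[i, Q_SC50K] ** r + kr)
            s_A = Ang / (p[i, Q_SC50A] + Ang)
            out[i, PD_ALDO] = p[i, Q_KGEN] * (1.0 + p[i, Q_SMAX] * s_K * s_A) \
                - p[i, Q_KDEG] * Aldo
            beta = p[i, Q_BETA]
            c = ((Fk / p[i, Q_FK0REF]) ** p[i, Q_GAMMA]
                 - (p[i, Q_FK0] / p[i, Q_FK0REF]) ** p[i, Q_GAMMA] + 1.0)
            ALD = (Aldo / p[i, Q_ALDO0] + beta * c) / (1.0 + beta)
            vr = Vec / p[i, Q_VEC0]
            Pa = 1.0 + p[i, Q_GP] * (vr - 1.0)
            GFR = 1.0 + p[i, Q_GGFR] * (Pa - 1.0)
            if GFR < 1e-6:
                GFR = 1e-6
            rt = 1.0 - p[i, Q_GR] * (Pa - 1.0)
            if rt < 0.0:
                rt = 0.0
            out[i, PD_PRA] = p[i, Q_KREN] * (rt - PRA)
            out[i, PD_ANG] = p[i, Q_KANG] * (p[i, Q_ANGII0] * PRA - Ang)
            fK = 1.0 + p[i, Q_GALDK] * (ALD - 1.0)
            if fK < 0.0:
                fK = 0.0
            fNa = 1.0 - p[i, Q_GALDNA] * (ALD - 1.0)
            if fNa < 0.0:
                fNa = 0.0
            yku = p[i, Q_IK] * GFR ** p[i, Q_AGFR] * (Ks_s / p[i, Q_KS0]) ** p[i, Q_BK] * fK
            ynu = p[i, Q_INA] * GFR ** p[i, Q_AGFR] * (Nas / p[i, Q_NA0]) ** p[i, Q_BNA] * fNa
            J_ic = p[i, Q_KX] * (p[i, Q_KS0] * (Kic / p[i, Q_AKIC0]) - Ks_s)
            out[i, PD_KEC] = p[i, Q_IK] - yku + J_ic
            out[i, PD_KIC] = -J_ic
            out[i, PD_NAEC] = p[i, Q_INA] - ynu
            out[i, PD_VEC] = p[i, Q_KW] * (p[i, Q_VEC0]
                                           * (1.0 + p[i, Q_HVOL] * (Naec / (p[i, Q_NA0] * p[i, Q_VEC0]) - 1.0))
                                           - Vec)
            out[i, PD_UK] = yku
            out[i, PD_UNA] = ynu
        else:
            for j in range(PD_FK, N_STATES):
                out[i, j] = 0.0


# ---------------------------------------------------------------------------
# parameter packing


def pack_human_params(config: ModelConfig, fistula: bool = False,
                      licorice: bool = False) -> np.ndarray:
    """Pack a human configuration into the compiled-RHS parameter row
    (PD block zeroed; see :func:`pack_pd_params`)."""
    if config.species != "human":
        raise ParameterError("human model requires a human parameter set")
    phys = config.physiology
    hct = config.compound("GL").hematocrit
    p = np.zeros(N_PARAMS)
    p[P_VPL] = phys.volumes["vascular"] * (1 - hct)
    p[P_VL] = phys.volumes["liver"]
    p[P_VVL] = phys.volumes["liver_venous"] * (1 - hct)
    p[P_Q] = phys.liver_blood_flow * (1 - hct)
    p[P_KST] = phys.transit["K_st"]
    p[P_KS] = phys.transit["K_s"]
    p[P_KCO] = phys.transit["K_co"]
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
        p[o + C_CLUP] = cp["CL_up"]
        p[o + C_CLB] = cp["CL_b"]
        p[o + C_CLMET] = cp["CL_met"]
        p[o + C_PSEFF] = cp["PS_eff"]
        p[o + C_KABSSI] = cp["K_abs_si"]
        p[o + C_KABSCO] = cp["K_abs_co"]
        p[o + C_KHCO] = cp["KH_co"]
        p[o + C_PK] = cp["P_k"]
    if licorice:
        p[OFF["GL"] + C_KHCO] *= 4.0
    return p


def pack_pd_params(p: np.ndarray, hsd2: Hsd2Params, raas: RaasParams,
                   ep: ElectrolyteParams) -> None:
    """Fill the PD block of a packed parameter row and switch PD on."""
    p[P_PDON] = 1.0
    p[Q_IC50] = hsd2.IC50 * 1000.0
    p[Q_KOX0] = hsd2.k_ox0
    p[Q_KURF] = hsd2.k_ur_F
    p[Q_KURE] = hsd2.k_ur_E
    p[Q_K0C] = hsd2.k_0
    p[Q_VKPD] = hsd2.V_k
    p[Q_VAPP] = hsd2.V_app
    p[Q_FK0] = hsd2.F_k0
    p[Q_E0] = hsd2.E_0
    p[Q_KGEN] = raas.K_gen_aldo
    p[Q_SMAX] = raas.S_max
    p[Q_SC50K] = raas.SC50_K
    p[Q_SC50A] = raas.SC50_AngII
    p[Q_KDEG] = raas.K_deg_aldo
    p[Q_RHILL] = raas.hill_K
    p[Q_ALDO0] = aldo_steady_state(ep.K_serum0, ep.AngII0, raas)
    p[Q_BETA] = ep.beta_cortisol
    p[Q_KS0] = ep.K_serum0
    p[Q_NA0] = ep.Na_serum0
    p[Q_ANGII0] = ep.AngII0
    p[Q_VEC0] = ep.V_ecf0
    p[Q_AKIC0] = ep.K_ic_pool0
    p[Q_IK] = ep.K_intake
    p[Q_INA] = ep.Na_intake
    p[Q_KX] = ep.k_exchange
    p[Q_KW] = ep.k_water
    p[Q_HVOL] = ep.h_volume
    p[Q_GP] = ep.g_pressure
    p[Q_GGFR] = ep.g_gfr
    p[Q_GR] = ep.g_renin
    p[Q_KREN] = ep.k_renin
    p[Q_KANG] = ep.k_angii
    p[Q_AGFR] = ep.a_gfr
    p[Q_BNA] = ep.b_na
    p[Q_GALDK] = ep.g_ald_K
    p[Q_GALDNA] = ep.g_ald_Na
    p[Q_BK] = ep.b_k
    p[Q_GAMMA] = ep.gamma_mr
    p[Q_FK0REF] = hsd2.F_k0_ref


def pd_initial_state(p: np.ndarray, Aldo_init: float | None = None) -> np.ndarray:
    """Baseline PD state slice matching a packed parameter row."""
    return np.array([
        p[Q_FK0], p[Q_E0], 0.0, 0.0,
        Aldo_init if Aldo_init is not None else p[Q_ALDO0],
        1.0, p[Q_ANGII0],
        p[Q_KS0] * p[Q_VEC0], p[Q_AKIC0], p[Q_NA0] * p[Q_VEC0], p[Q_VEC0],
        0.0, 0.0,
    ])


_DOSE_LAYOUT = {
    "GL": {"central": GL_X, "stomach": GL_ST},
    "GA": {"central": GA_X, "stomach": GA_ST},
    "GAM": {},
}

_GB_PAIRS = ((GL_GB, GL_SI), (GAM_GB, GAM_SI))


def build_human_system(config: ModelConfig, regimen: DoseRegimen,
                       t_end: float | None = None,
                       hsd2: Hsd2Params | None = None,
                       raas: RaasParams | None = None,
                       electrolyte: ElectrolyteParams | None = None,
                       dose_umol: float | np.ndarray | None = None,
                       n_batch: int = 1) -> OdeSystem:
    """Assemble the human system (PK only, or the full cascade when the PD
    parameter sets are provided). ``dose_umol`` may be a per-batch array."""
    for name in ("GL", "GA", "GAM"):
        config.compound(name)
    t_end = t_end if t_end is not None else 24.0 * regimen.n_days
    p = pack_human_params(config, fistula=regimen.bile_fistula,
                          licorice=regimen.licorice_matrix)
    pd_on = hsd2 is not None
    if pd_on:
        if raas is None or electrolyte is None:
            raise ParameterError("the PD cascade needs hsd2, raas and electrolyte parameters")
        pack_pd_params(p, hsd2, raas, electrolyte)
    if dose_umol is None:
        mw = config.compound(regimen.compound).molecular_weight
        dose_umol = regimen.dose_umol(mw)
    meal_times = regimen.meal_times
    if meal_times is None:
        meal_times = config.physiology.meal_times
    events = schedule_events(regimen, _DOSE_LAYOUT[regimen.compound], dose_umol,
                             t_end, meal_times=meal_times,
                             gallbladder_pairs=() if regimen.bile_fistula else _GB_PAIRS)
    P = np.tile(p, (n_batch, 1))
    return OdeSystem(state_names=STATE_NAMES, rhs=cascade_rhs, events=events,
                     params=P, compiled=True,
                     metadata={"species": "human", "regimen": regimen,
                               "t_end": t_end, "pd": pd_on})


def initial_state(system: OdeSystem, Aldo_init: float | None = None) -> np.ndarray:
    """Zero-drug initial state (m, n) for a built human system."""
    P = system.params
    y0 = np.zeros((P.shape[0], N_STATES))
    if system.metadata.get("pd"):
        for i in range(P.shape[0]):
            y0[i, PD_FK:] = pd_initial_state(P[i], Aldo_init)
    return y0


def _derived_series(p: np.ndarray):
    def fn(ts, states):
        out = {}
        for name, xi, ali, off in (("GL", GL_X, GL_AL, 10), ("GA", GA_X, GA_AL, 30)):
            if name == "GL":
                S = (p[off + C_PSEFF] * p[off + C_FUT] * states[:, GL_AL] / p[P_VL]
                     + p[off + C_KABSSI] * states[:, GL_SI])
            else:
                S = (p[off + C_PSEFF] * p[off + C_FUT] * states[:, GA_AL] / p[P_VL]
                     + p[off + C_KABSSI] * states[:, GA_SI]
                     + p[off + C_KABSCO] * states[:, GA_CO])
            D = p[P_Q] + p[off + C_FU] * p[off + C_CLUP]
            C = (states[:, xi] - p[P_VVL] * S / D) / (p[off + C_VEFF] + p[P_VVL] * p[P_Q] / D)
            C = np.maximum(C, 0.0)
            out[f"C_plasma_{name}"] = C
            out[f"C_kidney_{name}"] = p[off + C_PK] * C
        out["total_umol"] = (states[:, :FEC_GAM + 1].sum(axis=1)
                             + states[:, FIST_GL] + states[:, FIST_GAM])
        out["K_serum"] = np.divide(states[:, PD_KEC], states[:, PD_VEC],
                                   out=np.zeros(len(ts)), where=states[:, PD_VEC] > 0)
        out["Na_serum"] = np.divide(states[:, PD_NAEC], states[:, PD_VEC],
                                    out=np.zeros(len(ts)), where=states[:, PD_VEC] > 0)
        return out

    return fn


def simulate_human(config: ModelConfig, regimen: DoseRegimen, t_end: float | None = None,
                   step: float = 0.01, save_every: int = 10) -> TimeCourse:
    """Simulate a human regimen (PK only); plasma/kidney concentrations in
    umol/l, amounts umol."""
    system = build_human_system(config, regimen, t_end)
    y0 = initial_state(system)[0]
    return integrate(system, (0.0, system.metadata["t_end"]), step, y0,
                     save_every=save_every, series_fn=_derived_series(system.params[0]))


def simulate_cascade(config: ModelConfig, regimen: DoseRegimen,
                     hsd2: Hsd2Params, raas: RaasParams,
                     electrolyte: ElectrolyteParams,
                     t_end: float | None = None, Aldo_init: float | None = None,
                     step: float = 0.01, save_every: int = 25) -> TimeCourse:
    """Simulate the full PBPK -> 11beta-HSD2 -> RAAS/electrolyte cascade for
    one human regimen."""
    system = build_human_system(config, regimen, t_end, hsd2=hsd2, raas=raas,
                                electrolyte=electrolyte)
    y0 = initial_state(system, Aldo_init)[0]
    return integrate(system, (0.0, system.metadata["t_end"]), step, y0,
                     save_every=save_every, series_fn=_derived_series(system.params[0]))


def human_mass_balance_error(tc: TimeCourse, dosed_umol: float) -> float:
    total = tc.series["total_umol"]
    mask = total > 1e-9
    if dosed_umol <= 0:
        return float(np.max(np.abs(total))) if np.any(mask) else 0.0
    return float(np.max(np.abs(total[mask] - dosed_umol))) / dosed_umol


def default_human_config() -> ModelConfig:
    return load_parameters(species="human")


# ---------------------------------------------------------------------------
# interspecies scaling operations


@dataclass(frozen=True)
class ScalingSpec:
    """Rat -> human scaling factors."""

    BW_rat: float = 0.25
    BW_human: float = 70.0
    allometric_exponent: float = 0.75
    liver_weight_rat: float = 10.3     # ml ~ g
    liver_weight_human: float = 1800.0

    def __post_init__(self) -> None:
        if not 0.0 < self.allometric_exponent <= 1.0:
            raise ParameterError("allometric exponent must be in (0, 1]")
        for f in ("BW_rat", "BW_human", "liver_weight_rat", "liver_weight_human"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"scaling.{f} must be > 0")


def scale_clearance_allometric(CL_rat: float, spec: ScalingSpec = ScalingSpec()) -> float:
    """CL_human = CL_rat * (BW_human/BW_rat)^exponent (same unit as input)."""
    if CL_rat < 0:
        raise ParameterError("CL_rat must be >= 0")
    return CL_rat * (spec.BW_human / spec.BW_rat) ** spec.allometric_exponent


def scale_clmet_liver_weight(CL_human_in_vivo: float,
                             spec: ScalingSpec = ScalingSpec()) -> float:
    """Rat metabolic clearance from the human in-vivo value by liver-weight
    ratio. Derivation utility only: the published rat value is authoritative
    (this linear scaling recovers it to ~20%)."""
    return CL_human_in_vivo * spec.liver_weight_rat / spec.liver_weight_human


def microsomal_binding_correction(logD: float) -> float:
    """Unbound fraction in a microsomal incubation from lipophilicity.

    Standard relation log10((1 - fu)/fu) = 0.56*logD - 1.41, i.e. very
    hydrophilic compounds are fully unbound; monotone decreasing in logD.
    Utility for in-vitro to in-vivo clearance extrapolation.
    """
    if not np.isfinite(logD):
        raise ParameterError("logD must be finite")
    return 1.0 / (1.0 + 10.0 ** (0.56 * logD - 1.41))
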