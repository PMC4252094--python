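"""Reduced renin-angiotensin-aldosterone + body-fluid/electrolyte system.

Aldosterone release is driven by its two secretagogues, serum potassium
(steep Hill dependence) and angiotensin II (hyperbolic), combined
multiplicatively on top of a basal zero-order release with first-order
elimination. The mineralocorticoid-receptor (MR) signal combines aldosterone
with kidney cortisol (normalized, cortisol-weighted); it raises urinary
potassium excretion and lowers urinary sodium excretion. Sodium/water
retention expands the extracellular volume, raising the arterial-pressure
surrogate and the glomerular filtration rate and suppressing renin and hence
angiotensin II (the compensatory arm of pseudoaldosteronism). An
intracellular potassium pool buffers serum potassium through a first-order
exchange. All reduction gains live in one calibration config
(``data/electrolyte.yaml``); with no MR perturbation the system is an exact
fixed point by construction.

Units: K/Na mmol/l, aldosterone ng/dl, angiotensin II pg/ml, volumes l,
time h; pressure/GFR/renin are normalized surrogates (baseline 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hsd2 import Hsd2Params
from .ode import OdeSystem, TimeCourse, integrate
from .params import ParameterError, load_yaml


@dataclass(frozen=True)
class RaasParams:
    """Aldosterone secretagogue constants."""

    K_gen_aldo: float    # ng/dl/h zero-order release
    S_max: float         # maximal fold-stimulation
    SC50_K: float        # mmol/l
    SC50_AngII: float    # pg/ml
    K_deg_aldo: float    # 1/h
    hill_K: float        # Hill coefficient (potassium arm only)

    def __post_init__(self) -> None:
        for f in ("K_gen_aldo", "S_max", "SC50_K", "SC50_AngII", "K_deg_aldo", "hill_K"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"raas.{f} must be > 0")


@dataclass(frozen=True)
class ElectrolyteParams:
    """Baselines and reduction gains of the body-fluid/electrolyte block."""

    K_serum0: float
    Na_serum0: float
    AngII0: float
    V_ecf0: float
    K_ic_pool0: float
    K_intake: float      # mmol/h
    Na_intake: float     # mmol/h
    beta_cortisol: float
    gamma_mr: float
    g_pressure: float
    g_gfr: float
    g_renin: float
    k_renin: float
    k_angii: float
    a_gfr: float
    b_k: float
    b_na: float
    g_ald_K: float
    g_ald_Na: float
    k_exchange: float
    k_water: float
    h_volume: float

    def __post_init__(self) -> None:
        for f in ("K_serum0", "Na_serum0", "AngII0", "V_ecf0", "K_ic_pool0",
                  "K_intake", "Na_intake"):
            if getattr(self, f) <= 0:
                raise ParameterError(f"electrolyte.{f} must be > 0")


def default_raas_params(config: dict | None = None) -> RaasParams:
    doc = config or load_yaml("pd")
    r = doc["raas"]
    return RaasParams(K_gen_aldo=r["K_gen_aldo"], S_max=r["S_max"], SC50_K=r["SC50_K"],
                      SC50_AngII=r["SC50_AngII"], K_deg_aldo=r["K_deg_aldo"],
                      hill_K=r["hill_K"])


def default_electrolyte_params(K_serum0: float | None = None,
                               Na_serum0: float | None = None,
                               AngII0: float | None = None,
                               config: dict | None = None) -> ElectrolyteParams:
    """Electrolyte parameters from the calibration config, with optional
    scenario baselines (serum K/Na, angiotensin II)."""
    doc = config or load_yaml("electrolyte")
    b, g = doc["baselines"], doc["gains"]
    return ElectrolyteParams(
        K_serum0=K_serum0 if K_serum0 is not None else b["K_serum"],
        Na_serum0=Na_serum0 if Na_serum0 is not None else b["Na_serum"],
        AngII0=AngII0 if AngII0 is not None else b["AngII"],
        V_ecf0=b["V_ecf"], K_ic_pool0=b["K_intracellular_pool"],
        K_intake=b["K_intake"] / 24.0, Na_intake=b["Na_intake"] / 24.0,
        beta_cortisol=g["beta_cortisol"], gamma_mr=g["gamma_mr"],
        g_pressure=g["g_pressure"],
        g_gfr=g["g_gfr"], g_renin=g["g_renin"], k_renin=g["k_renin"],
        k_angii=g["k_angii"], a_gfr=g["a_gfr_excretion"], b_k=g["b_k"],
        b_na=g["b_na"],
        g_ald_K=g["g_ald_K"], g_ald_Na=g["g_ald_Na"], k_exchange=g["k_exchange"],
        k_water=g["k_water"], h_volume=g["h_volume"],
    )


# ---------------------------------------------------------------------------
# aldosterone secretagogue model


def secretagogue_stimulation(K_serum, AngII, params: RaasParams):
    """Product of the saturable potassium (Hill) and angiotensin II
    (hyperbolic) stimulation fractions."""
    K = np.asarray(K_serum, float)
    A = np.asarray(AngII, float)
    kr = K ** params.hill_K
    s_K = kr / (params.SC50_K ** params.hill_K + kr)
    s_A = A / (params.SC50_AngII + A)
    return s_K * s_A


def aldosterone_rhs(Aldo, K_serum, AngII, params: RaasParams):
    """d[Aldo]/dt = K_gen*(1 + S_max*s_K*s_AngII) - K_deg*[Aldo]."""
    if np.any(np.asarray(K_serum) < 0) or np.any(np.asarray(AngII) < 0):
        raise ParameterError("secretagogue concentrations must be >= 0")
    stim = secretagogue_stimulation(K_serum, AngII, params)
    return params.K_gen_aldo * (1.0 + params.S_max * stim) - params.K_deg_aldo * np.asarray(Aldo)


def aldo_steady_state(K_serum, AngII, params: RaasParams):
    """Closed-form aldosterone steady state at fixed K and AngII (ng/dl)."""
    stim = secretagogue_stimulation(K_serum, AngII, params)
    out = params.K_gen_aldo / params.K_deg_aldo * (1.0 + params.S_max * stim)
    return float(out) if np.ndim(out) == 0 else out


def mr_activation(Aldo, F_k, Aldo0: float, F_k0: float,
                  beta: float = 3.0, ALD0: float = 1.0,
                  gamma: float = 1.0, F_k0_ref: float | None = None):
    """Normalized MR signal from aldosterone plus kidney cortisol.

    ALD = ALD0 * (Aldo/Aldo0 + beta*c(F_k)) / (1 + beta) with the cortisol
    transduction c(F) = (F/F_ref)^gamma - (F_k0/F_ref)^gamma + 1, where
    ``F_k0`` is the subject's own baseline (so ALD = ALD0 there) and
    ``F_k0_ref`` the population-reference baseline. ``beta`` is the baseline
    cortisol:aldosterone contribution ratio (cortisol and aldosterone bind
    MR with equal affinity, and kidney cortisol is the dominant ligand once
    11beta-HSD2 is inhibited); ``gamma`` > 1 makes the transduction convex,
    so subjects with a higher baseline kidney cortisol (low 11beta-HSD2,
    elderly) respond more strongly to the same inhibition.
    """
    if Aldo0 <= 0 or F_k0 <= 0:
        raise ParameterError("MR baselines must be > 0")
    F_ref = F_k0_ref if F_k0_ref is not None else F_k0
    c = (np.asarray(F_k) / F_ref) ** gamma - (F_k0 / F_ref) ** gamma + 1.0
    out = ALD0 * (np.asarray(Aldo) / Aldo0 + beta * c) / (1.0 + beta)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# reduced electrolyte system

ELEC_STATES = ("Aldo", "PRA", "AngII", "K_ecf", "K_ic", "Na_ecf", "V_ecf",
               "U_K", "U_Na")


def electrolyte_fluxes(y, ALD, raas: RaasParams, ep: ElectrolyteParams, Aldo0: float):
    """Common right-hand-side terms of the electrolyte/RAAS block.

    ``y`` = (Aldo, PRA, AngII, K_ecf, K_ic, Na_ecf, V_ecf); returns their
    derivatives plus the urinary K and Na excretion rates.
    """
    Aldo, PRA, AngII, K_ecf, K_ic, Na_ecf, V_ecf = y
    Ks = K_ecf / V_ecf
    Nas = Na_ecf / V_ecf
    Na0_pool = ep.Na_serum0 * ep.V_ecf0
    dAldo = aldosterone_rhs(Aldo, Ks, AngII, raas)
    vr = V_ecf / ep.V_ecf0
    Pa = 1.0 + ep.g_pressure * (vr - 1.0)
    GFR = max(1.0 + ep.g_gfr * (Pa - 1.0), 1e-6)
    renin_target = max(1.0 - ep.g_renin * (Pa - 1.0), 0.0)
    dPRA = ep.k_renin * (renin_target - PRA)
    dAngII = ep.k_angii * (ep.AngII0 * PRA - AngII)
    yku = ep.K_intake * GFR ** ep.a_gfr * (Ks / ep.K_serum0) ** ep.b_k \
        * max(1.0 + ep.g_ald_K * (ALD - 1.0), 0.0)
    ynu = ep.Na_intake * GFR ** ep.a_gfr * (Nas / ep.Na_serum0) ** ep.b_na \
        * max(1.0 - ep.g_ald_Na * (ALD - 1.0), 0.0)
    J_ic = ep.k_exchange * (ep.K_serum0 * (K_ic / ep.K_ic_pool0) - Ks)
    dK = ep.K_intake - yku + J_ic
    dKic = -J_ic
    dNa = ep.Na_intake - ynu
    dV = ep.k_water * (ep.V_ecf0 * (1.0 + ep.h_volume * (Na_ecf / Na0_pool - 1.0)) - V_ecf)
    return (dAldo, dPRA, dAngII, dK, dKic, dNa, dV), yku, ynu


def build_electrolyte_system(raas: RaasParams, ep: ElectrolyteParams,
                             ald_fn=None) -> OdeSystem:
    """Electrolyte/RAAS system with an exogenous MR signal ``ald_fn(t)``
    (default: baseline 1, giving the global no-perturbation fixed point)."""
    Aldo0 = aldo_steady_state(ep.K_serum0, ep.AngII0, raas)
    if ald_fn is None:
        ald_fn = lambda t: 1.0  # noqa: E731

    def rhs(t, y):
        (dAldo, dPRA, dAngII, dK, dKic, dNa, dV), yku, ynu = electrolyte_fluxes(
            y[:7], float(ald_fn(t)), raas, ep, Aldo0)
        return np.array([dAldo, dPRA, dAngII, dK, dKic, dNa, dV, yku, ynu])

    return OdeSystem(state_names=list(ELEC_STATES), rhs=rhs,
                     metadata={"module": "electrolyte", "Aldo0": Aldo0})


def electrolyte_initial_state(raas: RaasParams, ep: ElectrolyteParams,
                              Aldo_init: float | None = None) -> np.ndarray:
    """Baseline state vector (the model fixed point; ``Aldo_init`` may set an
    observed baseline aldosterone as the initial value)."""
    Aldo0 = aldo_steady_state(ep.K_serum0, ep.AngII0, raas)
    return np.array([
        Aldo_init if Aldo_init is not None else Aldo0,
        1.0, ep.AngII0,
        ep.K_serum0 * ep.V_ecf0, ep.K_ic_pool0,
        ep.Na_serum0 * ep.V_ecf0, ep.V_ecf0,
        0.0, 0.0,
    ])


# ---------------------------------------------------------------------------
# full PD cascade (HSD2 -> MR -> RAAS/electrolytes) on an external GA series

PD_STATES = ("F_k", "E", "U_F", "U_E") + ELEC_STATES


def build_pd_system(ga_kidney_times: np.ndarray, ga_kidney_umol_l: np.ndarray,
                    hsd2: Hsd2Params, raas: RaasParams,
                    ep: ElectrolyteParams) -> OdeSystem:
    """Full PD system driven by an interpolated kidney-GA series (umol/l)."""
    ts = np.asarray(ga_kidney_times, float)
    cs = np.asarray(ga_kidney_umol_l, float)
    ic50 = hsd2.IC50 * 1000.0
    Aldo0 = aldo_steady_state(ep.K_serum0, ep.AngII0, raas)

    def rhs(t, y):
        C = np.interp(t, ts, cs)
        kox = hsd2.k_ox0 * (1.0 - C / (ic50 + C))
        F_k, E = y[0], y[1]
        dF = (hsd2.k_0 - (kox + hsd2.k_ur_F) * F_k) / hsd2.V_k
        dE = (kox * F_k - hsd2.k_ur_E * E) / hsd2.V_app
        ALD = mr_activation(y[4], F_k, Aldo0, hsd2.F_k0, beta=ep.beta_cortisol,
                            gamma=ep.gamma_mr, F_k0_ref=hsd2.F_k0_ref)
        (dAldo, dPRA, dAngII, dK, dKic, dNa, dV), yku, ynu = electrolyte_fluxes(
            y[4:11], ALD, raas, ep, Aldo0)
        return np.array([dF, dE, hsd2.k_ur_F * F_k, hsd2.k_ur_E * E,
                         dAldo, dPRA, dAngII, dK, dKic, dNa, dV, yku, ynu])

    return OdeSystem(state_names=list(PD_STATES), rhs=rhs,
                     metadata={"module": "pd_cascade", "Aldo0": Aldo0})


def simulate_pd_cascade(ga_kidney: TimeCourse, hsd2: Hsd2Params,
                        raas: RaasParams, ep: ElectrolyteParams,
                        key: str = "C_kidney_GA", t_end: float | None = None,
                        Aldo_init: float | None = None,
                        step: float = 0.01, save_every: int = 25) -> TimeCourse:
    """Couple a kidney-GA exposure time course through 11beta-HSD2 and the
    MR into the RAAS/electrolyte system.

    Returns angiotensin II (pg/ml), aldosterone (ng/dl), serum K and Na
    (mmol/l), kidney cortisol/plasma cortisone and cumulative urinary
    electrolytes over the regimen.
    """
    t_end = t_end if t_end is not None else float(ga_kidney.times[-1])
    system = build_pd_system(ga_kidney.times, ga_kidney.series[key], hsd2, raas, ep)
    y0 = np.concatenate([[hsd2.F_k0, hsd2.E_0, 0.0, 0.0],
                         electrolyte_initial_state(raas, ep, Aldo_init)])
    tc = integrate(system, (0.0, t_end), step, y0, save_every=save_every)
    tc.series["K_serum"] = tc.series["K_ecf"] / tc.series["V_ecf"]
    tc.series["Na_serum"] = tc.series["Na_ecf"] / tc.series["V_ecf"]
    return tc
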