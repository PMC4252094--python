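"""11beta-HSD2 inhibition module: kidney cortisol, plasma cortisone and the
24 h urinary cortisol:cortisone ratio driven by kidney GA concentration.

Cortisol is formed at a constant rate ``k_0`` and eliminated from the kidney
by 11beta-HSD2 oxidation (clearance ``k_ox``) and urinary excretion
(``k_ur_F``); cortisone appears only by that oxidation and leaves by urinary
excretion (``k_ur_E``) from an apparent volume ``V_app``. GA inhibits the
oxidation with a saturable Imax-1 law. Baseline clearances are derived from
the baseline plasma concentrations and 24 h urinary excretions so that the
drug-free system is an exact fixed point.

Units: concentrations ug/l, clearances l/h, amounts ug; kidney GA in
umol/ml (published IC50 units) for the public operation, umol/l internally
in the compiled cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ode import OdeSystem, TimeCourse, integrate
from .params import ParameterError, load_yaml


@dataclass(frozen=True)
class Hsd2Params:
    """Cortisol/cortisone kinetic constants (l/h, ug/l, ug/h) plus the GA
    inhibition constant IC50 (umol/ml kidney tissue)."""

    IC50: float
    k_ox0: float
    k_ur_F: float
    k_ur_E: float
    k_0: float
    V_k: float
    V_app: float
    F_0: float
    E_0: float
    F_k0: float
    K_tp_cortisol: float
    urinary_cortisol_24h: float
    urinary_cortisone_24h: float
    #: population-reference baseline kidney cortisol (the normal-adult value;
    #: equals F_k0 for a reference subject). Used to normalize the MR signal.
    F_k0_ref: float = 0.0

    def __post_init__(self) -> None:
        for name in ("IC50", "k_ox0", "k_ur_F", "k_ur_E", "k_0", "V_k", "V_app",
                     "F_0", "E_0", "F_k0", "K_tp_cortisol"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"hsd2.{name} must be > 0, got {getattr(self, name)}")
        if self.F_k0_ref <= 0:
            object.__setattr__(self, "F_k0_ref", self.F_k0)

    @property
    def baseline_urinary_ratio(self) -> float:
        """R at baseline: (k_ur_F*F_k0)/(k_ur_E*E_0) = U_F/U_E."""
        return (self.k_ur_F * self.F_k0) / (self.k_ur_E * self.E_0)


def inhibited_kox(C_ga_kidney: float | np.ndarray, params: Hsd2Params) -> float | np.ndarray:
    """11beta-HSD2 clearance under GA inhibition: k_ox0*(1 - C/(IC50+C)).

    ``C_ga_kidney`` in umol/ml kidney tissue (the IC50 unit).
    """
    C = np.asarray(C_ga_kidney, dtype=float)
    if np.any(C < 0):
        raise ParameterError("kidney GA concentration must be >= 0")
    out = params.k_ox0 * (1.0 - C / (params.IC50 + C))
    return float(out) if out.ndim == 0 else out


def derive_baseline_params(
    F_0: float,
    E_0: float,
    K_tp_cortisol: float,
    urinary_cortisol_24h: float,
    urinary_cortisone_24h: float,
    V_k: float = 0.3,
    V_app: float = 5.2,
    IC50: float = 0.000234,
    k_ox0: float | None = None,
) -> Hsd2Params:
    """Close the baseline equilibria and return a consistent parameter set.

    * ``F_k0 = K_tp * F_0`` (kidney:plasma partition of cortisol) for the
      normal-adult reference subject
    * ``k_ur_F`` from the 24 h urinary cortisol over the kidney baseline
    * ``k_ur_E`` from the 24 h urinary cortisone over plasma cortisone, and
      the reference ``k_ox0`` from the cortisone balance (formation =
      excretion at equilibrium)
    * ``k_0`` closes the cortisol balance.

    With ``k_ox0`` given (e.g. the elderly value 0.02 l/h), the subject is
    derived from that reference via :func:`with_kox0`: cortisol production
    and urinary clearances are population properties, so a lower baseline
    11beta-HSD2 clearance raises the subject's baseline kidney cortisol and
    lowers plasma cortisone (a higher plasma cortisol:cortisone ratio, the
    sampled elderly trait). The returned parameters make the drug-free
    system an exact fixed point.
    """
    for name, v in (("F_0", F_0), ("E_0", E_0), ("K_tp_cortisol", K_tp_cortisol),
                    ("urinary_cortisol_24h", urinary_cortisol_24h),
                    ("urinary_cortisone_24h", urinary_cortisone_24h)):
        if v <= 0:
            raise ParameterError(f"baseline {name} must be > 0, got {v}")
    F_k0 = K_tp_cortisol * F_0
    k_ur_F = urinary_cortisol_24h / (24.0 * F_k0)
    k_ur_E = urinary_cortisone_24h / (24.0 * E_0)
    k_ox0_ref = k_ur_E * E_0 / F_k0
    k_0 = (k_ox0_ref + k_ur_F) * F_k0
    ref = Hsd2Params(
        IC50=IC50, k_ox0=k_ox0_ref, k_ur_F=k_ur_F, k_ur_E=k_ur_E, k_0=k_0,
        V_k=V_k, V_app=V_app, F_0=F_0, E_0=E_0, F_k0=F_k0,
        K_tp_cortisol=K_tp_cortisol,
        urinary_cortisol_24h=urinary_cortisol_24h,
        urinary_cortisone_24h=urinary_cortisone_24h,
        F_k0_ref=F_k0,
    )
    if k_ox0 is None:
        return ref
    return with_kox0(ref, k_ox0)


def default_hsd2_params(elderly: bool = False, config: dict | None = None) -> Hsd2Params:
    """Build Hsd2Params from the shipped PD config."""
    doc = config or load_yaml("pd")
    h = doc["hsd2"]
    b = h["baselines"]
    return derive_baseline_params(
        F_0=b["F_0"], E_0=b["E_0"], K_tp_cortisol=b["K_tp_cortisol"],
        urinary_cortisol_24h=b["urinary_cortisol_24h"],
        urinary_cortisone_24h=b["urinary_cortisone_24h"],
        V_k=h["V_k"], V_app=h["V_app"], IC50=h["IC50"],
        k_ox0=h["k_ox0_elderly"] if elderly else None,
    )


STATE_NAMES = ("F_k", "E", "U_F", "U_E")


def build_hsd2_system(ga_kidney_times: np.ndarray, ga_kidney_umol_l: np.ndarray,
                      params: Hsd2Params) -> OdeSystem:
    """Cortisol/cortisone subsystem driven by an external kidney-GA series
    (umol/l, linearly interpolated; held at its last value beyond the span)."""
    ts = np.asarray(ga_kidney_times, float)
    cs = np.asarray(ga_kidney_umol_l, float)
    ic50 = params.IC50 * 1000.0  # umol/ml -> umol/l

    def rhs(t, y):
        C = np.interp(t, ts, cs)
        kox = params.k_ox0 * (1.0 - C / (ic50 + C))
        F_k, E = y[0], y[1]
        return np.array([
            (params.k_0 - (kox + params.k_ur_F) * F_k) / params.V_k,
            (kox * F_k - params.k_ur_E * E) / params.V_app,
            params.k_ur_F * F_k,
            params.k_ur_E * E,
        ])

    return OdeSystem(state_names=list(STATE_NAMES), rhs=rhs,
                     metadata={"module": "hsd2"})


def simulate_cortisol_cortisone(ga_kidney: TimeCourse, params: Hsd2Params,
                                key: str = "C_kidney_GA", t_end: float | None = None,
                                step: float = 0.01, save_every: int = 10) -> TimeCourse:
    """Integrate kidney cortisol and plasma cortisone under a kidney-GA
    exposure time course (series ``key`` in umol/l)."""
    t_end = t_end if t_end is not None else float(ga_kidney.times[-1])
    system = build_hsd2_system(ga_kidney.times, ga_kidney.series[key], params)
    y0 = np.array([params.F_k0, params.E_0, 0.0, 0.0])
    tc = integrate(system, (0.0, t_end), step, y0, save_every=save_every)
    tc.series["urinary_flux_F"] = params.k_ur_F * tc.series["F_k"]
    tc.series["urinary_flux_E"] = params.k_ur_E * tc.series["E"]
    return tc


def urinary_ratio_24h(tc: TimeCourse, day: int) -> float:
    """24 h urinary cortisol:cortisone ratio over simulated ``day`` (1-based).

    R = (U_F(24d) - U_F(24(d-1))) / (U_E(24d) - U_E(24(d-1))) using the
    cumulative urinary series.
    """
    lo, hi = 24.0 * (day - 1), 24.0 * day
    if lo < tc.times[0] - 1e-9 or hi > tc.times[-1] + 1e-9:
        raise ValueError(f"day {day} outside simulated span")
    uf = np.interp([lo, hi], tc.times, tc.series["U_F"])
    ue = np.interp([lo, hi], tc.times, tc.series["U_E"])
    denom = ue[1] - ue[0]
    if denom <= 0:
        raise ZeroDivisionError("no urinary cortisone excreted over the requested day")
    return float((uf[1] - uf[0]) / denom)


def with_kox0(params: Hsd2Params, k_ox0: float) -> Hsd2Params:
    """Derive a subject with a different baseline 11beta-HSD2 clearance.

    Cortisol production (k_0) and the urinary clearances are held at their
    population values; the subject's baseline kidney cortisol and plasma
    cortisone re-equilibrate: F_k0 = k_0/(k_ox0 + k_ur_F),
    E_0 = k_ox0*F_k0/k_ur_E. The population reference F_k0_ref is preserved
    for the MR normalization.
    """
    if k_ox0 <= 0:
        raise ParameterError("k_ox0 must be > 0")
    F_k0 = params.k_0 / (k_ox0 + params.k_ur_F)
    E_0 = k_ox0 * F_k0 / params.k_ur_E
    return replace(params, k_ox0=k_ox0, F_k0=F_k0, E_0=E_0,
                   F_0=F_k0 / params.K_tp_cortisol,
                   F_k0_ref=params.F_k0_ref)
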