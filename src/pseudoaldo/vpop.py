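"""Virtual elderly population: sensitivity-factor sampling, per-subject
hypokalemia dose limits, lognormal fitting, the curvature-based critical
dose and exceedance probabilities, plus the one-at-a-time sensitivity
scenarios.

A subject is a triple (CL_up multiplier, colonic transit constant K_co,
baseline 11beta-HSD2 clearance k_ox0). The dose limit is the daily oral GL
dose that brings serum potassium to the hypokalemia boundary (3.5 mmol/l)
on day 28, found by bisection on a monotone dose-response; the whole cohort
is bisected in one batched integration per iteration. Dose limits are
summarized by a maximum-likelihood lognormal fit (mu, sigma), the critical
dose at maximal curvature of the cumulative distribution, and the
probability of hypokalemia at query doses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import humanmodel as hm
from .hsd2 import default_hsd2_params, with_kox0
from .ode import integrate_batch
from .params import DoseRegimen, ModelConfig, ParameterError, load_yaml
from .raas import default_electrolyte_params, default_raas_params


@dataclass(frozen=True)
class SensitivityDistributions:
    """Distributions of the three sensitivity factors.

    CL_up multiplier: lognormal with median 1 (sigma from the published
    4.9-fold 95% range); K_co: bootstrap over a configurable sample vector
    (1/h); k_ox0: truncated normal with bounds at the sample extremes (l/h).
    """

    cl_up_sigma: float
    kco_samples: tuple[float, ...]
    kox0_mean: float
    kox0_sd: float
    kox0_lower: float
    kox0_upper: float

    def __post_init__(self) -> None:
        if self.cl_up_sigma <= 0:
            raise ParameterError("cl_up_sigma must be > 0")
        if len(self.kco_samples) == 0:
            raise ParameterError("K_co bootstrap sample vector must be non-empty")
        if not self.kox0_lower < self.kox0_upper:
            raise ParameterError("k_ox0 truncation bounds must satisfy lower < upper")


def default_distributions(config: dict | None = None) -> SensitivityDistributions:
    doc = config or load_yaml("vpop")
    return SensitivityDistributions(
        cl_up_sigma=doc["cl_up_multiplier"]["sigma_log"],
        kco_samples=tuple(doc["K_co"]["samples"]),
        kox0_mean=doc["k_ox0"]["mean"], kox0_sd=doc["k_ox0"]["sd"],
        kox0_lower=doc["k_ox0"]["lower"], kox0_upper=doc["k_ox0"]["upper"],
    )


def sample_subjects(n: int, dists: SensitivityDistributions, seed: int) -> pd.DataFrame:
    """Draw ``n`` virtual subjects; reproducible under ``seed``."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cl = np.exp(rng.normal(0.0, dists.cl_up_sigma, size=n))
    kco = rng.choice(np.asarray(dists.kco_samples), size=n, replace=True)
    a = (dists.kox0_lower - dists.kox0_mean) / dists.kox0_sd
    b = (dists.kox0_upper - dists.kox0_mean) / dists.kox0_sd
    kox0 = stats.truncnorm.rvs(a, b, loc=dists.kox0_mean, scale=dists.kox0_sd,
                               size=n, random_state=rng)
    return pd.DataFrame({"cl_up_multiplier": cl, "K_co": kco, "k_ox0": kox0})


# ---------------------------------------------------------------------------
# cohort simulation


def _cohort_params(config: ModelConfig, subjects: pd.DataFrame,
                   baseline_K: float, pd_config: dict | None = None) -> np.ndarray:
    """Packed per-subject parameter rows for the 28-day cascade."""
    base = hm.pack_human_params(config)
    hsd2 = default_hsd2_params(elderly=True, config=pd_config)
    raas = default_raas_params(config=pd_config)
    ep = default_electrolyte_params(K_serum0=baseline_K)
    hm.pack_pd_params(base, hsd2, raas, ep)
    P = np.tile(base, (len(subjects), 1))
    P[:, hm.OFF["GL"] + hm.C_CLUP] *= subjects["cl_up_multiplier"].to_numpy()
    P[:, hm.OFF["GA"] + hm.C_CLUP] *= subjects["cl_up_multiplier"].to_numpy()
    P[:, hm.P_KCO] = subjects["K_co"].to_numpy()
    for i, k in enumerate(subjects["k_ox0"].to_numpy()):
        h = with_kox0(hsd2, float(k))
        P[i, hm.Q_KOX0] = h.k_ox0
        P[i, hm.Q_FK0] = h.F_k0
        P[i, hm.Q_E0] = h.E_0
    return P


def _k_day_end(P: np.ndarray, dose_mg: np.ndarray, config: ModelConfig,
               eval_day: int, step: float) -> np.ndarray:
    """Serum potassium (mmol/l) at the end of ``eval_day`` for each subject
    dosed daily with ``dose_mg`` oral GL."""
    regimen = DoseRegimen(compound="GL", route="po", dose_amount=1.0,
                          n_days=eval_day)
    mw = config.compound("GL").molecular_weight
    dose_umol = np.asarray(dose_mg, float) / mw * 1000.0
    system = hm.build_human_system(config, regimen, t_end=24.0 * eval_day,
                                   dose_umol=dose_umol)
    system.params = P
    y0 = np.zeros((P.shape[0], hm.N_STATES))
    for i in range(P.shape[0]):
        y0[i, hm.PD_FK:] = hm.pd_initial_state(P[i])
    _, Y = integrate_batch(system, (0.0, 24.0 * eval_day), step, y0, save_every=0)
    yf = Y[-1]
    return yf[:, hm.PD_KEC] / yf[:, hm.PD_VEC]


def dose_limit_batch(subjects: pd.DataFrame, config: ModelConfig | None = None,
                     threshold: float = 3.5, eval_day: int = 28,
                     dose_bracket: tuple[float, float] = (10.0, 2000.0),
                     tol: float = 1.0, baseline_K: float = 4.18,
                     step: float = 0.02, pd_config: dict | None = None) -> pd.DataFrame:
    """Bisection dose limits for a whole cohort (one batched run per iteration).

    Returns the subjects frame extended with ``dose_limit`` (mg/day; NaN for
    censored subjects), ``censored_low`` (K below threshold already at the
    bracket low end) and ``censored_high`` (K never crosses at the high end).
    """
    config = config or hm.default_human_config()
    P = _cohort_params(config, subjects, baseline_K, pd_config)
    n = len(subjects)
    lo = np.full(n, dose_bracket[0])
    hi = np.full(n, dose_bracket[1])
    k_lo = _k_day_end(P, lo, config, eval_day, step)
    k_hi = _k_day_end(P, hi, config, eval_day, step)
    cens_low = k_lo <= threshold
    cens_high = k_hi > threshold
    active = ~(cens_low | cens_high)
    while np.any((hi - lo)[active] > tol):
        mid = np.sqrt(lo * hi)
        k_mid = _k_day_end(P, mid, config, eval_day, step)
        above = k_mid > threshold
        lo = np.where(active & above, mid, lo)
        hi = np.where(active & ~above, mid, hi)
    out = subjects.copy()
    out["dose_limit"] = np.where(active, np.sqrt(lo * hi), np.nan)
    out["censored_low"] = cens_low
    out["censored_high"] = cens_high
    out["K_at_bracket_low"] = k_lo
    out["K_at_bracket_high"] = k_hi
    return out


def dose_limit(subject: dict | pd.Series, threshold: float = 3.5, eval_day: int = 28,
               dose_bracket: tuple[float, float] = (10.0, 2000.0), tol: float = 1.0,
               baseline_K: float = 4.18, config: ModelConfig | None = None,
               step: float = 0.02) -> float:
    """Daily oral GL dose (mg) giving serum K = ``threshold`` on ``eval_day``
    for one subject. Raises when the bracket does not straddle the threshold."""
    df = pd.DataFrame([dict(subject)])
    res = dose_limit_batch(df, config=config, threshold=threshold, eval_day=eval_day,
                           dose_bracket=dose_bracket, tol=tol, baseline_K=baseline_K,
                           step=step)
    row = res.iloc[0]
    if row["censored_low"] or row["censored_high"]:
        raise ParameterError(
            f"dose bracket {dose_bracket} does not straddle K={threshold} mmol/l "
            f"on day {eval_day}: K({dose_bracket[0]} mg)={row['K_at_bracket_low']:.3f}, "
            f"K({dose_bracket[1]} mg)={row['K_at_bracket_high']:.3f}"
        )
    return float(row["dose_limit"])


# ---------------------------------------------------------------------------
# distribution summaries


def fit_lognormal(doses) -> tuple[float, float]:
    """Maximum-likelihood lognormal fit: mu = mean(ln d), sigma = sd(ln d)."""
    d = np.asarray(doses, float)
    if d.size < 2:
        raise ParameterError("need at least 2 dose limits to fit")
    if np.any(d <= 0):
        raise ParameterError("dose limits must be > 0")
    logs = np.log(d)
    return float(np.mean(logs)), float(np.std(logs))


def critical_dose(mu: float, sigma: float) -> float:
    """Dose at the maximum of the second derivative of the lognormal CDF.

    Closed form x* = exp(mu - u*sigma^2) with u = (3 + sqrt(1 + 4/sigma^2))/2
    (the left inflection of the density, where risk starts rising steeply).
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    u = (3.0 + math.sqrt(1.0 + 4.0 / sigma ** 2)) / 2.0
    return math.exp(mu - u * sigma ** 2)


def critical_dose_numeric(mu: float, sigma: float, n_grid: int = 200001) -> float:
    """Grid argmax of d2(CDF)/dx2 = d(pdf)/dx; numerical cross-check of the
    closed form."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    x = np.linspace(math.exp(mu - 4 * sigma), math.exp(mu), n_grid)
    pdf = stats.lognorm.pdf(x, s=sigma, scale=math.exp(mu))
    dpdf = np.gradient(pdf, x)
    return float(x[np.argmax(dpdf)])


def probability_at_dose(mu: float, sigma: float, dose: float,
                        round_percent: bool = False) -> float:
    """Hypokalemia probability (percent) at a daily dose: 100*Phi((ln d - mu)/sigma)."""
    if dose <= 0:
        raise ParameterError("dose must be > 0")
    pct = 100.0 * stats.norm.cdf((math.log(dose) - mu) / sigma)
    return float(round(pct)) if round_percent else float(pct)


def run_vpop(n: int = 1000, seed: int = 0, threshold: float = 3.5, eval_day: int = 28,
             dose_bracket: tuple[float, float] = (10.0, 2000.0), tol: float = 1.0,
             step: float = 0.02, config: ModelConfig | None = None,
             dists: SensitivityDistributions | None = None,
             query_doses: tuple[float, ...] = (100.0, 101.0, 200.0)) -> dict:
    """Full Monte Carlo pipeline: sample subjects, find dose limits, fit the
    lognormal, compute the critical dose and query-dose probabilities."""
    vcfg = load_yaml("vpop")
    dists = dists or default_distributions(vcfg)
    baseline_K = vcfg["dose_limit"]["baseline_K"]
    subjects = sample_subjects(n, dists, seed)
    res = dose_limit_batch(subjects, config=config, threshold=threshold,
                           eval_day=eval_day, dose_bracket=dose_bracket, tol=tol,
                           baseline_K=baseline_K, step=step)
    doses = res["dose_limit"].dropna().to_numpy()
    if doses.size < 2:
        raise ParameterError("fewer than 2 uncensored dose limits; cannot fit")
    mu, sigma = fit_lognormal(doses)
    crit = critical_dose(mu, sigma)
    return {
        "subjects": res,
        "doses": doses,
        "n_censored_low": int(res["censored_low"].sum()),
        "n_censored_high": int(res["censored_high"].sum()),
        "mu": mu,
        "sigma": sigma,
        "mu_se": sigma / math.sqrt(doses.size),
        "critical_dose": crit,
        "probabilities": {d: probability_at_dose(mu, sigma, d) for d in query_doses},
        "seed": seed,
    }


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity scenarios


def sensitivity_scenarios(factor_grid: dict[str, list[float]] | None = None,
                          dose_mg: float = 200.0, n_days: int = 7,
                          step: float = 0.02,
                          config: ModelConfig | None = None) -> pd.DataFrame:
    """Run daily oral GL for each factor level and report GA plasma AUC and
    final-day serum potassium.

    Default grid: CL_up multiplier {1/2.21, 1, 2.21}; K_co {normal, elderly
    0.0217}; k_ox0 {normal 0.036, elderly 0.02} (one factor varied at a
    time, the others at their normal values).
    """
    config = config or hm.default_human_config()
    hsd2 = default_hsd2_params()
    kco_normal = config.physiology.transit["K_co"]
    if factor_grid is None:
        factor_grid = {
            "cl_up_multiplier": [1.0 / 2.21, 1.0, 2.21],
            "K_co": [kco_normal, 0.0217],
            "k_ox0": [hsd2.k_ox0, 0.02],
        }
    rows = []
    for factor, values in factor_grid.items():
        for v in values:
            subj = {"cl_up_multiplier": 1.0, "K_co": kco_normal, "k_ox0": hsd2.k_ox0}
            subj[factor] = v
            df = pd.DataFrame([subj])
            P = _cohort_params(config, df, baseline_K=4.18)
            regimen = DoseRegimen(compound="GL", route="po", dose_amount=dose_mg,
                                  n_days=n_days)
            mw = config.compound("GL").molecular_weight
            system = hm.build_human_system(config, regimen, t_end=24.0 * n_days,
                                           dose_umol=np.array([dose_mg / mw * 1e3]))
            system.params = P
            y0 = np.zeros((1, hm.N_STATES))
            y0[0, hm.PD_FK:] = hm.pd_initial_state(P[0])
            ts, Y = integrate_batch(system, (0.0, 24.0 * n_days), step, y0,
                                    save_every=25)
            sfn = hm._derived_series(P[0])
            series = sfn(ts, Y[:, 0, :])
            ga_auc = float(np.trapezoid(series["C_plasma_GA"], ts))
            k_end = float(Y[-1, 0, hm.PD_KEC] / Y[-1, 0, hm.PD_VEC])
            rows.append({"factor": factor, "value": v,
                         "ga_plasma_auc_umol_h_l": ga_auc,
                         "K_final_mmol_l": k_end})
    return pd.DataFrame(rows)
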