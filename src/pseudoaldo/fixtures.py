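"""Synthetic concentration datasets and a parameter-recovery harness.

The published calibration datasets exist only as figures, so model-fitting
is exercised on synthetic fixtures: simulate a known parameter set, sample
at stated times, apply multiplicative lognormal noise (seeded), then refit
selected parameters by least squares and compare with the truth.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import humanmodel, ratmodel
from .params import DoseRegimen, ModelConfig, ParameterError


def _simulate(config: ModelConfig, regimen: DoseRegimen, t_end: float, step: float):
    if config.species == "rat":
        return ratmodel.simulate_rat(config, regimen, t_end=t_end, step=step)
    return humanmodel.simulate_human(config, regimen, t_end=t_end, step=step)


def generate_fixture(config: ModelConfig, regimen: DoseRegimen,
                     sample_times: np.ndarray, noise_cv: float, seed: int,
                     series: str = "C_plasma_GL", step: float = 0.01) -> pd.DataFrame:
    """Synthetic sampled concentrations with multiplicative lognormal noise.

    ``noise_cv`` is the coefficient of variation; 0 returns the simulator
    output exactly. Columns: time_h, compartment, value, unit.
    """
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    ts = np.asarray(sample_times, float)
    tc = _simulate(config, regimen, float(ts.max()), step)
    clean = np.interp(ts, tc.times, tc.series[series])
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sd = np.sqrt(np.log(1.0 + noise_cv ** 2))
        clean = clean * np.exp(rng.normal(-0.5 * sd * sd, sd, size=ts.size))
    unit = "umol/ml" if config.species == "rat" else "umol/l"
    return pd.DataFrame({"time_h": ts, "compartment": series, "value": clean,
                         "unit": unit})


def _with_compound_values(config: ModelConfig, compound: str, **values) -> ModelConfig:
    cp = replace(config.compounds[compound], **values)
    comps = dict(config.compounds)
    comps[compound] = cp
    return replace(config, compounds=comps)


def fit_compound_params(dataset: pd.DataFrame, config: ModelConfig,
                        regimen: DoseRegimen, compound: str = "GL",
                        free: tuple[str, ...] = ("V_max", "K_12_r", "K_21_r"),
                        x0_scale: float = 1.5, step: float = 0.02) -> dict[str, float]:
    """Refit selected compound parameters to a fixture dataset.

    Least squares on log concentrations over log-parameters, started from
    the config values perturbed by ``x0_scale``. Returns the fitted values.
    """
    series = dataset["compartment"].iloc[0]
    ts = dataset["time_h"].to_numpy()
    obs = np.log(np.maximum(dataset["value"].to_numpy(), 1e-12))
    base = config.compounds[compound]

    def residuals(logx):
        vals = {f: float(np.exp(v)) for f, v in zip(free, logx)}
        cfg = _with_compound_values(config, compound, **vals)
        tc = _simulate(cfg, regimen, float(ts.max()), step)
        sim = np.interp(ts, tc.times, tc.series[series])
        return np.log(np.maximum(sim, 1e-12)) - obs

    x0 = np.log([getattr(base, f) * x0_scale for f in free])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-10, ftol=1e-10)
    return {f: float(np.exp(v)) for f, v in zip(free, sol.x)}
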