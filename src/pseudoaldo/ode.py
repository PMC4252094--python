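"""Fixed-step RK4 integration of compartmental systems with discrete events.

Two drivers share the same scheme:

* a pure-Python driver for arbitrary callable right-hand sides (used by the
  small pharmacodynamic subsystems and in tests), and
* a numba-compiled batch driver for the compiled PBPK/PD right-hand sides,
  which integrates many parameter sets simultaneously (the Monte Carlo
  virtual-population engine runs whole cohorts through one call).

Events (doses, meal-triggered gallbladder emptying) are instantaneous state
transformations applied exactly at their scheduled times; the integrator
refines the step grid so every event time is a grid point. A scipy adaptive
solver is wrapped as an independent cross-check
(:func:`integrate_adaptive`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .params import DoseRegimen, ParameterError

log = logging.getLogger(__name__)

#: states may transiently undershoot zero by this fraction of their running
#: peak and are clamped (with a logged warning); larger undershoot aborts.
CLAMP_TOL = 1e-9
ERROR_TOL = 1e-6


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Event:
    """An instantaneous state transformation at ``time``.

    ``add`` maps state index -> amount to add (dose events); ``transfer``
    is a list of (source, destination) index pairs whose full source content
    is moved (gallbladder emptying). Amounts may be scalars or per-batch
    arrays.
    """

    time: float
    add: Mapping[int, float | np.ndarray] = field(default_factory=dict)
    transfer: tuple[tuple[int, int], ...] = ()
    label: str = ""

    def apply(self, y: np.ndarray) -> None:
        # y is (n,) or (m, n); operate on the last axis
        for idx, amount in self.add.items():
            y[..., idx] += amount
        for src, dst in self.transfer:
            y[..., dst] += y[..., src]
            y[..., src] = 0.0


@dataclass
class OdeSystem:
    """A compartmental ODE system.

    ``rhs`` is either a Python callable ``f(t, y) -> dy`` over a 1-D state,
    or a numba dispatcher ``f(t, Y, P, out)`` over a batched ``(m, n)``
    state with per-batch parameter rows ``P``. ``params`` holds the packed
    parameter array for compiled systems.
    """

    state_names: Sequence[str]
    rhs: Callable
    events: list[Event] = field(default_factory=list)
    params: np.ndarray | None = None
    compiled: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    def index(self, name: str) -> int:
        return list(self.state_names).index(name)


@dataclass
class TimeCourse:
    """Integrated trajectories: strictly increasing times plus named series."""

    times: np.ndarray
    series: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for k, v in self.series.items():
            if v.shape[0] != self.times.shape[0]:
                raise ValueError(f"series {k!r} length {v.shape[0]} != times {len(self.times)}")

    def __getitem__(self, key: str) -> np.ndarray:
        return self.series[key]

    def interp(self, key: str, t: float | np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, self.series[key])

    def auc(self, key: str, window: tuple[float, float] | None = None) -> float:
        """Trapezoid-rule AUC of a series, optionally over ``window`` (h)."""
        t, v = self.times, self.series[key]
        if window is not None:
            lo, hi = window
            if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
                raise ValueError(f"window {window} outside simulated span ({t[0]}, {t[-1]})")
            grid = np.unique(np.concatenate([[lo, hi], t[(t > lo) & (t < hi)]]))
            v = np.interp(grid, t, v)
            t = grid
        return float(np.trapezoid(v, t))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, **{k: v for k, v in self.series.items()}})

    def to_csv(self, path, fmt: str = "%.9g") -> None:
        """Write as CSV with fixed decimal formatting for byte-stable output."""
        df = self.to_frame()
        df.to_csv(path, index=False, float_format=fmt.replace("%", "%%") if False else fmt)


# ---------------------------------------------------------------------------
# event scheduling

_ROUTE_TARGETS = {"iv": "central", "po": "stomach", "ip": "depot"}


def schedule_events(
    regimen: DoseRegimen,
    layout: Mapping[str, int],
    dose_umol: float | np.ndarray,
    t_end: float,
    meal_times: Sequence[float] = (),
    gallbladder_pairs: Sequence[tuple[int, int]] = (),
) -> list[Event]:
    """Expand a dosing regimen into discrete events.

    ``layout`` maps the roles ``central`` (i.v. target), ``stomach`` (p.o.
    target) and ``depot`` (i.p. target) of the dosed compound to state
    indices; missing roles raise (e.g. a rat regimen trying to dose GAM).
    ``gallbladder_pairs`` are (store, lumen) index pairs emptied at each meal
    time of each simulated day.
    """
    role = _ROUTE_TARGETS[regimen.route]
    if role not in layout:
        raise ParameterError(
            f"route {regimen.route!r} is not supported for compound "
            f"{regimen.compound!r} in this model"
        )
    target = layout[role]
    events: list[Event] = []
    for day in range(regimen.n_days):
        for t in regimen.dose_times:
            tt = 24.0 * day + t
            if tt <= t_end:
                events.append(Event(time=tt, add={target: dose_umol},
                                    label=f"dose {regimen.compound} {regimen.route}"))
    if gallbladder_pairs:
        n_meal_days = int(math.ceil(t_end / 24.0))
        for day in range(n_meal_days):
            for t in meal_times:
                tt = 24.0 * day + t
                if tt <= t_end:
                    events.append(Event(time=tt, transfer=tuple(gallbladder_pairs),
                                        label="meal (gallbladder emptying)"))
    return sorted(events, key=lambda e: e.time)


# ---------------------------------------------------------------------------
# numba batch driver


@njit(cache=True, fastmath=True)
def _rk4_span_nb(rhs, y, p, t0, t1, nstep, peak, rec, rec_pos, rec_every):
    """Integrate y (m, n) over [t0, t1] with nstep uniform RK4 steps.

    Records into ``rec`` (nrec, m, n) every ``rec_every`` steps when
    ``rec_every > 0``. Returns (new rec_pos, worst relative undershoot).
    """
    m, n = y.shape
    h = (t1 - t0) / nstep
    k1 = np.empty((m, n))
    k2 = np.empty((m, n))
    k3 = np.empty((m, n))
    k4 = np.empty((m, n))
    yt = np.empty((m, n))
    worst = 0.0
    for s in range(nstep):
        t = t0 + s * h
        rhs(t, y, p, k1)
        for i in range(m):
            for j in range(n):
                yt[i, j] = y[i, j] + 0.5 * h * k1[i, j]
        rhs(t + 0.5 * h, yt, p, k2)
        for i in range(m):
            for j in range(n):
                yt[i, j] = y[i, j] + 0.5 * h * k2[i, j]
        rhs(t + 0.5 * h, yt, p, k3)
        for i in range(m):
            for j in range(n):
                yt[i, j] = y[i, j] + h * k3[i, j]
        rhs(t + h, yt, p, k4)
        for i in range(m):
            for j in range(n):
                v = y[i, j] + (h / 6.0) * (k1[i, j] + 2.0 * k2[i, j] + 2.0 * k3[i, j] + k4[i, j])
                if not math.isfinite(v):
                    return rec_pos, -1.0
                if v < 0.0:
                    ref = peak[i, j] if peak[i, j] > 1e-12 else 1.0
                    rel = -v / ref
                    if rel > worst:
                        worst = rel
                    v = 0.0
                y[i, j] = v
                if v > peak[i, j]:
                    peak[i, j] = v
        if rec_every > 0 and (s + 1) % rec_every == 0:
            for i in range(m):
                for j in range(n):
                    rec[rec_pos, i, j] = y[i, j]
            rec_pos += 1
    return rec_pos, worst


def _segments(t_span, events, step):
    """Break [t0, t1] at event times; yield (t_start, t_end, events_at_start)."""
    t0, t1 = t_span
    times = sorted({e.time for e in events if t0 <= e.time <= t1} | {t0, t1})
    by_time: dict[float, list[Event]] = {}
    for e in events:
        if t0 <= e.time <= t1:
            by_time.setdefault(e.time, []).append(e)
    segs = []
    for a, b in zip(times[:-1], times[1:]):
        segs.append((a, b, by_time.get(a, [])))
    trailing = by_time.get(times[-1], []) if times[-1] == t1 else []
    return segs, trailing


def _check_undershoot(worst: float, t: float) -> None:
    if worst < 0:
        raise IntegrationError(f"non-finite derivative encountered near t={t:.4g} h")
    if worst > ERROR_TOL:
        raise IntegrationError(
            f"state undershoot {worst:.2e} of peak (>{ERROR_TOL}) near t={t:.4g} h"
        )
    if worst > CLAMP_TOL:
        log.warning("clamped negative state (%.2e of peak) near t=%.4g h", worst, t)


def integrate_batch(
    system: OdeSystem,
    t_span: tuple[float, float],
    step: float,
    y0: np.ndarray,
    save_every: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched RK4 for compiled systems.

    ``y0`` is (m, n) and is not modified. With ``save_every == 0`` only the
    final state is recorded. Returns ``(times, Y)`` with ``Y`` of shape
    (nt, m, n).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    y = np.array(y0, dtype=np.float64)
    if y.ndim != 2:
        raise ValueError("integrate_batch expects a (m, n) state")
    p = system.params
    peak = np.maximum(y.copy(), 0.0)
    segs, trailing = _segments(t_span, system.events, step)
    times: list[float] = [t_span[0]]
    recs: list[np.ndarray] = []
    rec0 = y.copy()
    # pre-count record slots
    total = 0
    plan = []
    for a, b, evs in segs:
        nstep = max(1, int(math.ceil((b - a) / step - 1e-12)))
        plan.append((a, b, evs, nstep))
        if save_every > 0:
            total += nstep // save_every
    nrec = max(total, 1)
    rec = np.empty((nrec, y.shape[0], y.shape[1]))
    pos = 0
    for a, b, evs, nstep in plan:
        for e in evs:
            e.apply(y)
            np.maximum(peak, y, out=peak)
        h = (b - a) / nstep
        every = save_every if save_every > 0 else 0
        if every > 0:
            for s in range(nstep // every):
                times.append(a + (s + 1) * every * h)
        pos, worst = _rk4_span_nb(system.rhs, y, p, a, b, nstep, peak, rec, pos, every)
        _check_undershoot(worst, b)
    for e in trailing:
        e.apply(y)
    if save_every > 0:
        ts = np.asarray(times)
        Y = np.concatenate([rec0[None], rec[:pos]], axis=0)
        if abs(ts[-1] - t_span[1]) > 1e-9:
            ts = np.append(ts, t_span[1])
            Y = np.concatenate([Y, y[None]], axis=0)
        else:
            Y[-1] = y
        return ts, Y
    return np.asarray([t_span[0], t_span[1]]), np.stack([rec0, y])


# ---------------------------------------------------------------------------
# python driver (1-D state, callable rhs)


def integrate(
    system: OdeSystem,
    t_span: tuple[float, float],
    step: float,
    y0: Sequence[float],
    save_every: int = 1,
    series_fn: Callable[[np.ndarray, np.ndarray], dict[str, np.ndarray]] | None = None,
) -> TimeCourse:
    """Integrate a system with fixed-step RK4, applying events on the grid.

    For compiled systems this delegates to the batch driver with m=1. The
    returned TimeCourse contains one series per state name (plus any extra
    series computed by ``series_fn(times, states)``).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    y0 = np.asarray(y0, dtype=float)
    if system.compiled:
        ts, Y = integrate_batch(system, t_span, step, y0[None, :], save_every=max(save_every, 1))
        states = Y[:, 0, :]
    else:
        ts, states = _integrate_py(system, t_span, step, y0, save_every)
    series = {name: states[:, i] for i, name in enumerate(system.state_names)}
    if series_fn is not None:
        series.update(series_fn(ts, states))
    meta = dict(system.metadata)
    meta.update(step=step, t_span=t_span)
    return TimeCourse(times=ts, series=series, metadata=meta)


def _integrate_py(system, t_span, step, y0, save_every):
    y = y0.copy()
    f = system.rhs
    peak = np.maximum(y, 0.0)
    segs, trailing = _segments(t_span, system.events, step)
    times = [t_span[0]]
    states = [y.copy()]
    count = 0
    for a, b, evs in segs:
        for e in evs:
            e.apply(y)
            np.maximum(peak, y, out=peak)
        nstep = max(1, int(math.ceil((b - a) / step - 1e-12)))
        h = (b - a) / nstep
        for s in range(nstep):
            t = a + s * h
            k1 = np.asarray(f(t, y))
            k2 = np.asarray(f(t + 0.5 * h, y + 0.5 * h * k1))
            k3 = np.asarray(f(t + 0.5 * h, y + 0.5 * h * k2))
            k4 = np.asarray(f(t + h, y + h * k3))
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if not np.all(np.isfinite(y)):
                bad = np.flatnonzero(~np.isfinite(y))
                raise IntegrationError(
                    f"non-finite state {list(np.asarray(system.state_names)[bad])} at t={t + h:.4g} h"
                )
            neg = y < 0
            if np.any(neg):
                ref = np.where(peak > 1e-12, peak, 1.0)
                worst = float(np.max(-y[neg] / ref[neg]))
                _check_undershoot(worst, t + h)
                y[neg] = 0.0
            np.maximum(peak, y, out=peak)
            count += 1
            if count % save_every == 0:
                times.append(t + h)
                states.append(y.copy())
    for e in trailing:
        e.apply(y)
    if abs(times[-1] - t_span[1]) > 1e-9:
        times.append(t_span[1])
        states.append(y.copy())
    else:
        states[-1] = y.copy()
    return np.asarray(times), np.asarray(states)


# ---------------------------------------------------------------------------
# adaptive reference integrator (independent cross-check)


def integrate_adaptive(
    system: OdeSystem,
    t_span: tuple[float, float],
    y0: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    t_eval_step: float | None = None,
) -> TimeCourse:
    """Integrate with a scipy adaptive solver, honouring the same events.

    Serves as the independent reference for the fixed-step RK4 scheme; not
    batched.
    """
    y = np.asarray(y0, dtype=float).copy()
    if system.compiled:
        p = system.params
        out = np.empty((1, y.size))

        def f(t, yy):
            system.rhs(t, yy[None, :].copy(), p, out)
            return out[0].copy()
    else:
        f = system.rhs
    segs, trailing = _segments(t_span, system.events, 1.0)
    times = [t_span[0]]
    states = [y.copy()]
    for a, b, evs in segs:
        for e in evs:
            e.apply(y)
        t_eval = None
        if t_eval_step:
            t_eval = np.arange(a, b, t_eval_step)[1:]
            t_eval = np.append(t_eval, b)
        sol = solve_ivp(f, (a, b), y, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:
            raise IntegrationError(f"adaptive solver failed on [{a}, {b}]: {sol.message}")
        for tt, yy in zip(sol.t[1:], sol.y.T[1:]):
            times.append(tt)
            states.append(yy)
        y = sol.y[:, -1].copy()
        y[y < 0] = 0.0
    for e in trailing:
        e.apply(y)
    states[-1] = y
    ts = np.asarray(times)
    keep = np.concatenate([[True], np.diff(ts) > 0])
    st = np.asarray(states)[keep]
    series = {name: st[:, i] for i, name in enumerate(system.state_names)}
    return TimeCourse(times=ts[keep], series=series, metadata=dict(system.metadata))
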