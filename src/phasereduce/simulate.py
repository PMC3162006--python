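"""Transient-protocol simulation, steady states and timecourse normalization.

The transient protocol is the single on/off input switch used throughout the
analysis: the input parameter is raised to its "on" value at ``t_on``,
returned to its "off" value at ``t_off``, and the combined on+off window is
what closes the phase loops.  Integration is piecewise over the two segments
with the parameter switched between them, which keeps the stiff solver away
from a discontinuous right-hand side.

Implicit algebraic states are handled as a semi-explicit index-1 DAE: at
every right-hand-side evaluation their residual equations are re-solved
(warm-started from the previous solution) so that the reported trajectories
satisfy the constraints at all output times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .models import ModelError, NetworkModel

__all__ = [
    "StimulusProtocol",
    "TimeCourseSet",
    "NormalizedTimeCourseSet",
    "SimulationError",
    "SteadyStateError",
    "simulate_transient",
    "find_steady_state",
    "normalize",
]

RTOL = 1e-8          # relative integration tolerance
ATOL = 1e-10         # absolute integration tolerance, µM
SS_RATE_TOL = 1e-8   # steady-state criterion, s⁻¹ (normalized rate)
STATIC_ATOL = 1e-9   # below this dynamic range a trace is "static"


class SimulationError(RuntimeError):
    """Integrator or constraint failure, annotated with the failing time."""


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge or diverged."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Single-switch transient input: on at ``t_on``, off at ``t_off``.

    ``parameter`` names the switched model parameter; values are in that
    parameter's units (µM for a ligand concentration, µM s⁻¹ for a source
    flux).  ``n_out`` output samples are spread uniformly over
    [t_on, t_end]; 2000 samples keep loop areas grid-converged to <1e-3.
    """

    parameter: str
    on_value: float
    off_value: float = 0.0
    t_on: float = 0.0
    t_off: float = 10.0
    t_end: float = 20.0
    n_out: int = 2000

    def __post_init__(self):
        if not (0 <= self.t_on < self.t_off <= self.t_end):
            raise ValueError("need 0 <= t_on < t_off <= t_end")
        if self.n_out < 3:
            raise ValueError("n_out must be >= 3")

    def describe(self) -> str:
        return (f"{self.parameter}: {self.off_value:g}->{self.on_value:g} at "
                f"t={self.t_on:g}s, ->{self.off_value:g} at t={self.t_off:g}s, "
                f"until t={self.t_end:g}s")


@dataclass
class TimeCourseSet:
    """Trajectories of every model state on a shared time grid.

    ``data`` is a DataFrame indexed by time (s) with one column per state
    (µM).  ``provenance`` records the model name and protocol description.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        t = self.data.index.to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if self.data.isna().any().any():
            raise ValueError("timecourses contain missing entries")

    @property
    def time(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    @property
    def states(self) -> list[str]:
        return list(self.data.columns)

    def __getitem__(self, state: str) -> np.ndarray:
        return self.data[state].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "time_s", self.time)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, provenance: str = "") -> "TimeCourseSet":
        df = pd.read_csv(path, sep=None, engine="python")
        if "time_s" not in df.columns:
            raise ValueError("timecourse file must have a 'time_s' column")
        df = df.set_index("time_s")
        df.index.name = None
        return cls(data=df, provenance=provenance or str(path))


@dataclass
class NormalizedTimeCourseSet(TimeCourseSet):
    """Per-state affine rescaling of a TimeCourseSet onto [0, 1].

    ``ranges`` stores each state's (x_min, x_max) for de-normalization;
    ``static_states`` lists states whose trace was constant and were
    excluded from normalization (and from phase analysis).
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    static_states: list[str] = field(default_factory=list)

    def denormalize(self, state: str) -> np.ndarray:
        lo, hi = self.ranges[state]
        return lo + self[state] * (hi - lo)


def normalize(tc: TimeCourseSet) -> NormalizedTimeCourseSet:
    """Rescale each trace by x_norm = (x − x_min)/(x_max − x_min).

    A trace whose dynamic range is numerically zero cannot be rescaled; it
    is flagged static and dropped rather than divided by zero.
    """
    cols, ranges, static = {}, {}, []
    for s in tc.states:
        x = tc[s]
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi - lo <= STATIC_ATOL * max(1.0, abs(hi)):
            static.append(s)
            continue
        cols[s] = (x - lo) / (hi - lo)
        ranges[s] = (lo, hi)
    data = pd.DataFrame(cols, index=tc.data.index)
    return NormalizedTimeCourseSet(
        data=data,
        provenance=tc.provenance + " [normalized]",
        ranges=ranges,
        static_states=static,
    )


# ---------------------------------------------------------------------------
# DAE right-hand side


class _DAESystem:
    """Integrator view of a model: ode states explicit, implicit states
    re-solved at every evaluation (index-1 semi-explicit treatment)."""

    def __init__(self, model: NetworkModel, z_guess: np.ndarray | None = None):
        self.model = model
        self.ode = model.ode_states
        self.alg = model.implicit_states
        self._z = (np.zeros(len(self.alg)) if z_guess is None
                   else np.array(z_guess, dtype=float))

    def _full(self, x: np.ndarray) -> np.ndarray:
        m = self.model
        y = np.zeros(len(m.states))
        for s, v in zip(self.ode, x):
            y[m.index(s)] = v
        if self.alg:
            y = self._solve_algebraic(y)
        return m.fill_full_state(y)

    def _solve_algebraic(self, y: np.ndarray) -> np.ndarray:
        m = self.model

        def res(z):
            yy = y.copy()
            for s, v in zip(self.alg, z):
                yy[m.index(s)] = v
            m.fill_full_state(yy)
            return m.residuals(yy)

        # MINPACK's finite-difference step scales with |x|, so denormally
        # small warm starts stall it; retry from zero (absolute step) and a
        # unit guess, and judge convergence by the residual, not the flag
        sol = None
        for guess in (self._z, np.zeros_like(self._z),
                      np.ones_like(self._z)):
            sol = root(res, guess, method="hybr", tol=1e-12)
            ok = (np.all(np.isfinite(sol.x))
                  and (sol.success
                       or np.max(np.abs(res(sol.x)), initial=0.0) < 1e-9))
            if ok:
                break
        else:
            raise SimulationError(
                f"algebraic solve failed for states {self.alg}: {sol.message}")
        self._z = sol.x
        for s, v in zip(self.alg, sol.x):
            y[m.index(s)] = v
        return y

    def __call__(self, t: float, x: np.ndarray) -> np.ndarray:
        y = self._full(np.asarray(x, dtype=float))
        return self.model.rhs(t, y)

    def full_trajectory(self, t: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Expand integrator output (n_ode, nt) to full-state (n_states, nt)."""
        out = np.empty((len(self.model.states), len(t)))
        for j in range(len(t)):
            out[:, j] = self._full(x[:, j])
        return out


def _integrate_segment(sys_: _DAESystem, t0, t1, x0, t_eval):
    sol = solve_ivp(sys_, (t0, t1), x0, method="BDF",
                    t_eval=t_eval, rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise SimulationError(
            f"integration failed near t={sol.t[-1] if len(sol.t) else t0:.6g}s: "
            f"{sol.message}")
    return sol


def find_steady_state(
    model: NetworkModel,
    param_overrides: Mapping[str, float] | None = None,
    *,
    x0: Mapping[str, float] | None = None,
    max_horizon: float = 1e6,
    magnitude_cap: float = 1e9,
) -> dict[str, float]:
    """Steady state of the dynamic system with the given overrides applied.

    Integrates from the initial guess over geometrically growing horizons
    until the scale-free rate criterion max |dx/dt| / max(|x|, 1 µM) falls
    below 1e-8 s⁻¹, then polishes with a root solve on the combined
    derivative+residual system.  Returns a full state mapping (explicit and
    parameterized states included).
    """
    m = model.with_params(param_overrides or {})
    dyn = m.dynamic_states
    init = dict(m.initial)
    if x0:
        init.update(x0)
    sys_ = _DAESystem(m)
    x = np.array([init.get(s, 0.0) for s in m.ode_states])
    # warm-start implicit states from the initial guess
    if m.implicit_states:
        sys_._z = np.array([init.get(s, 0.0) for s in m.implicit_states])

    def normrate(xv):
        y = sys_._full(xv)
        dx = m.rhs(0.0, y)
        scale = np.maximum(np.abs([y[m.index(s)] for s in m.ode_states]), 1.0)
        return float(np.max(np.abs(dx) / scale)) if len(dx) else 0.0

    horizon = 10.0
    while True:
        if not m.ode_states or normrate(x) < SS_RATE_TOL:
            break
        sol = _integrate_segment(sys_, 0.0, horizon, x, None)
        x = sol.y[:, -1]
        if np.max(np.abs(x), initial=0.0) > magnitude_cap:
            raise SteadyStateError(
                f"divergence: a state exceeded {magnitude_cap:g} µM")
        horizon *= 10.0
        if horizon > max_horizon * 10:
            raise SteadyStateError(
                f"no steady state within horizon {max_horizon:g}s "
                f"(residual rate {normrate(x):.3g}/s)")

    # polish: root of [ode derivs; residuals] over the dynamic states
    def fun(v):
        y = np.zeros(len(m.states))
        for s, val in zip(dyn, v):
            y[m.index(s)] = val
        m.fill_full_state(y)
        return np.concatenate([m.rhs(0.0, y), m.residuals(y)])

    v0 = np.array([x[m.ode_states.index(s)] if s in m.ode_states
                   else sys_._z[m.implicit_states.index(s)] for s in dyn])
    if len(dyn):
        sol = root(fun, v0, method="hybr", tol=1e-13)
        v = sol.x if sol.success else v0
        # tiny negative round-off from the polish is clipped
        v = np.where((v < 0) & (v > -1e-9), 0.0, v)
    else:
        v = v0
    y = m.full_state(dict(zip(dyn, v)))
    return {s: float(y[m.index(s)]) for s in m.states}


def simulate_transient(
    model: NetworkModel,
    protocol: StimulusProtocol,
    *,
    initial_state: Mapping[str, float] | None = None,
) -> TimeCourseSet:
    """Simulate the single-switch transient protocol.

    The initial condition is the resting steady state with the input at its
    off value (computed by :func:`find_steady_state` unless supplied).  The
    two protocol segments are integrated separately with the switched
    parameter updated in between, and all states — including explicit and
    parameterized ones — are reported on the shared output grid.
    """
    if protocol.parameter not in model.params:
        raise ModelError(
            f"protocol parameter {protocol.parameter!r} not in model params")
    rest = initial_state or find_steady_state(
        model, {protocol.parameter: protocol.off_value})
    t = np.linspace(protocol.t_on, protocol.t_end, protocol.n_out)
    on_mask = t <= protocol.t_off

    m_on = model.with_params({protocol.parameter: protocol.on_value})
    sys_on = _DAESystem(m_on)
    if m_on.implicit_states:
        sys_on._z = np.array([rest[s] for s in m_on.implicit_states])
    x0 = np.array([rest[s] for s in m_on.ode_states])

    t_on_grid = t[on_mask]
    # evaluate through t_off so the handoff state is exact, then trim
    pad = len(t_on_grid) == 0 or t_on_grid[-1] < protocol.t_off
    t_eval_on = (np.append(t_on_grid, protocol.t_off) if pad else t_on_grid)
    seg = _integrate_segment(sys_on, protocol.t_on, protocol.t_off, x0,
                             t_eval_on)
    x_switch = seg.y[:, -1]
    n_keep = len(t_on_grid)
    seg_t, seg_y = seg.t[:n_keep], seg.y[:, :n_keep]
    full_on = sys_on.full_trajectory(seg_t, seg_y)

    m_off = model.with_params({protocol.parameter: protocol.off_value})
    sys_off = _DAESystem(m_off, z_guess=sys_on._z)
    t_off_grid = t[~on_mask]
    if len(t_off_grid):
        seg2 = _integrate_segment(sys_off, protocol.t_off, protocol.t_end,
                                  x_switch, t_off_grid)
        full_off = sys_off.full_trajectory(seg2.t, seg2.y)
        full = np.concatenate([full_on, full_off], axis=1)
        tt = np.concatenate([seg_t, seg2.t])
    else:
        full, tt = full_on, seg_t

    data = pd.DataFrame(full.T, index=tt, columns=model.states)
    _check_trajectory(model, data)
    return TimeCourseSet(
        data=data,
        provenance=f"{model.name} | {protocol.describe()}",
    )


def _check_trajectory(model: NetworkModel, data: pd.DataFrame) -> None:
    """Positivity and conservation checks over the output grid."""
    neg = data.min()
    bad = neg[neg < -1e-7]
    if len(bad):
        raise SimulationError(
            f"negative concentration for {bad.index[0]!r}: {bad.iloc[0]:.3g} µM")
    if model.conserved_totals:
        arr = data.to_numpy()
        for j in range(arr.shape[0]):
            viol = model.check_conservation(arr[j])
            if viol:
                raise SimulationError(
                    f"conservation of {viol[0]!r} violated at "
                    f"t={data.index[j]:.6g}s")
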