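"""Numerical integration of compiled systems and steady-state location.

A fixed-step classical 4th-order Runge-Kutta integrator is used deliberately:
trajectories are bit-stable across runs, the convergence order is testable on
a dt ladder, and linear systems behave predictably (RK4 is exact for
polynomial right-hand sides up to cubic in t).  Trajectories record every
property of the network — forces and flows, not just the states — because
those are the physiologically named quantities a modeller wants to see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .compiler import ODESystem
from .errors import DivergedError, NonConstantSourceError, NoSteadyStateError


@dataclass
class Trajectory:
    """Time grid plus the value of every property at every grid point."""

    time: np.ndarray
    values: Dict[str, np.ndarray]

    def final(self, prop_id: str) -> float:
        return float(self.values[prop_id][-1])

    def write_csv(self, path) -> None:
        """CSV writer: first column `time`, one column per property id."""
        cols = sorted(self.values)
        with open(path, "w") as fh:
            fh.write("time," + ",".join(cols) + "\n")
            for i, t in enumerate(self.time):
                row = ",".join(repr(float(self.values[c][i])) for c in cols)
                fh.write(f"{t!r},{row}\n")


def _rk4_step(sys: ODESystem, t: float, y: np.ndarray, dt: float) -> np.ndarray:
    k1, _ = sys.rhs(t, y)
    k2, _ = sys.rhs(t + dt / 2.0, y + dt / 2.0 * k1)
    k3, _ = sys.rhs(t + dt / 2.0, y + dt / 2.0 * k2)
    k4, _ = sys.rhs(t + dt, y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def integrate(sys: ODESystem, t_end: float, dt: float,
              y0: Optional[np.ndarray] = None) -> Trajectory:
    """Fixed-step RK4 from t=0 to t_end, recording all properties per step.

    Raises E_DIVERGED on non-finite values (with the offending time) and
    propagates E_NEGATIVE_STATE from the mass-action law.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    n_steps = max(1, int(round(t_end / dt)))
    y = sys.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()

    times = np.empty(n_steps + 1)
    prop_ids = sorted(sys.network.properties)
    series: Dict[str, np.ndarray] = {p: np.empty(n_steps + 1) for p in prop_ids}

    t = 0.0
    for i in range(n_steps + 1):
        _, vals = sys.rhs(t, y)
        times[i] = t
        for p in prop_ids:
            series[p][i] = vals[p]
        if i == n_steps:
            break
        y = _rk4_step(sys, t, y, dt)
        t = (i + 1) * dt
        if not np.all(np.isfinite(y)):
            raise DivergedError(f"non-finite state at t={t}")
    return Trajectory(times, series)


def steady_state(sys: ODESystem, t_max: float = 100.0, tol: float = 1e-12,
                 dt: Optional[float] = None) -> Dict[str, float]:
    """Integrate a constant-source system until the state derivative vanishes.

    Returns the value of every property at the converged point.  Requires
    constant sources (E_NONCONSTANT_SOURCE otherwise); raises
    E_NO_STEADY_STATE if the max-norm of the derivative never falls below
    ``tol`` by ``t_max`` — e.g. for an undamped LC oscillator.
    """
    if not sys.constant_sources_only():
        raise NonConstantSourceError("steady_state requires constant sources")
    if dt is None:
        dt = t_max / 1e4
    y = sys.initial_state()
    t = 0.0
    while True:
        dydt, vals = sys.rhs(t, y)
        if len(y) == 0 or float(np.max(np.abs(dydt))) < tol:
            return vals
        if t >= t_max:
            raise NoSteadyStateError(
                f"derivative max-norm {np.max(np.abs(dydt)):.3g} at t_max={t_max}")
        y = _rk4_step(sys, t, y, dt)
        t += dt
        if not np.all(np.isfinite(y)):
            raise DivergedError(f"non-finite state at t={t}")
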