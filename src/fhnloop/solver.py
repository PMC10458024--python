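"""Trajectory container and ODE integration (adaptive embedded RK and fixed RK4).

Time is dimensionless throughout; conversion to milliseconds lives in
:mod:`fhnloop.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = ["SolverConfig", "Trajectory", "IntegrationError", "integrate"]

#: Default ceiling on the adaptive step; keeps the integrator honest across
#: the slope discontinuity of g at u = 0.
DEFAULT_MAX_STEP = 0.05


class IntegrationError(RuntimeError):
    """Integration failed (step underflow or non-finite state).

    Carries ``last_time``, the last time the solver reached successfully.
    """

    def __init__(self, message: str, last_time: float):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class SolverConfig:
    """Integrator settings.

    method
        "adaptive_embedded_rk" (Dormand-Prince RK45) or "fixed_rk4"
        (classic 4th-order Runge-Kutta with step = ``max_step``).
    rel_tol, abs_tol
        Adaptive-method tolerances.  Defaults are tight because limit-cycle
        periods feed frequency metrics and must be stable to well under 1%.
    max_step
        Step ceiling for the adaptive method; the exact step for fixed_rk4.
    horizon
        Integration length in dimensionless time.
    sample_dt
        Spacing of the uniform output grid.
    """

    method: str = "adaptive_embedded_rk"
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float = DEFAULT_MAX_STEP
    horizon: float = 500.0
    sample_dt: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in ("adaptive_embedded_rk", "fixed_rk4"):
            raise ValueError(f"unknown method {self.method!r}")
        if not (self.rel_tol > 0 and self.abs_tol > 0):
            raise ValueError("tolerances must be > 0")
        if not (self.max_step > 0 and self.horizon > 0 and self.sample_dt > 0):
            raise ValueError("max_step, horizon and sample_dt must be > 0")
        if self.sample_dt > self.horizon:
            raise ValueError("sample_dt must not exceed horizon")


@dataclass
class Trajectory:
    """Uniformly sampled solution of a 2- or 4-variable system.

    ``states`` has one row per time, one column per state variable
    (u, v for one unit; u1, v1, u2, v2 for the coupled system).  ``meta``
    records what produced the trajectory (parameters, coupling, solver
    config, seed) for provenance.
    """

    times: np.ndarray
    states: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or len(self.times) != self.states.shape[0]:
            raise ValueError("states must be 2-D with one row per time sample")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_vars(self) -> int:
        return self.states.shape[1]

    def channel(self, index: int) -> np.ndarray:
        """One state column (0 = u or u1, 1 = v or v1, 2 = u2, 3 = v2)."""
        return self.states[:, index]

    def after(self, t0: float) -> "Trajectory":
        """Restriction to times >= t0 (used for transient discard)."""
        mask = self.times >= t0
        return Trajectory(self.times[mask], self.states[mask], dict(self.meta))

    def column_names(self) -> list[str]:
        if self.n_vars == 2:
            return ["t", "u", "v"]
        if self.n_vars == 4:
            return ["t", "u1", "v1", "u2", "v2"]
        return ["t"] + [f"x{i}" for i in range(self.n_vars)]


def _rk4(field: Callable, y0: np.ndarray, t_grid: np.ndarray, h: float) -> np.ndarray:
    """Classic RK4 marched at fixed step h, sampled onto t_grid.

    Steps land exactly on every output time by splitting the last step
    before each grid point.
    """
    y = np.array(y0, dtype=float)
    out = np.empty((len(t_grid), len(y)))
    out[0] = y
    t = t_grid[0]
    for i in range(1, len(t_grid)):
        target = t_grid[i]
        while t < target - 1e-15:
            step = min(h, target - t)
            k1 = np.asarray(field(t, y))
            k2 = np.asarray(field(t + step / 2, y + step / 2 * k1))
            k3 = np.asarray(field(t + step / 2, y + step / 2 * k2))
            k4 = np.asarray(field(t + step, y + step * k3))
            y = y + step / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += step
            if not np.all(np.isfinite(y)):
                raise IntegrationError("non-finite state in fixed_rk4", t)
        t = target
        out[i] = y
    return out


def integrate(
    field: Callable[[float, np.ndarray], Sequence[float]],
    init: Sequence[float],
    cfg: SolverConfig,
    meta: dict | None = None,
) -> Trajectory:
    """Integrate ``dy/dt = field(t, y)`` from ``init`` over ``cfg.horizon``.

    Returns the solution on the uniform grid ``0, sample_dt, ..., horizon``.
    Deterministic for a fixed configuration.
    """
    y0 = np.asarray(init, dtype=float)
    if not np.all(np.isfinite(y0)):
        raise ValueError("initial state must be finite")
    n_steps = int(round(cfg.horizon / cfg.sample_dt))
    t_grid = np.linspace(0.0, n_steps * cfg.sample_dt, n_steps + 1)

    if cfg.method == "fixed_rk4":
        states = _rk4(field, y0, t_grid, cfg.max_step)
    else:
        sol = solve_ivp(
            field,
            (t_grid[0], t_grid[-1]),
            y0,
            method="RK45",
            t_eval=t_grid,
            rtol=cfg.rel_tol,
            atol=cfg.abs_tol,
            max_step=cfg.max_step,
        )
        if not sol.success:
            last = float(sol.t[-1]) if len(sol.t) else 0.0
            raise IntegrationError(f"adaptive integration failed: {sol.message}", last)
        states = sol.y.T
        if not np.all(np.isfinite(states)):
            raise IntegrationError("non-finite state in adaptive integration", float(sol.t[-1]))

    full_meta = {"solver": {
        "method": cfg.method, "rel_tol": cfg.rel_tol, "abs_tol": cfg.abs_tol,
        "max_step": cfg.max_step, "horizon": cfg.horizon, "sample_dt": cfg.sample_dt,
    }}
    if meta:
        full_meta.update(meta)
    return Trajectory(t_grid, states, full_meta)
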