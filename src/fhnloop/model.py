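"""Single-unit FitzHugh-Nagumo model with a piecewise-linear recovery nullcline.

The unit is the dimensionless two-variable system

    du/dt = f(u) - v + drive,      f(u) = u - u^3 / 3
    dv/dt = eps * (g(u) - v) - I,  g(u) = alpha*u (u < 0), beta*u (u >= 0)

where ``u`` is the fast membrane-potential-like variable, ``v`` the slow
recovery (ionic-current) variable, ``I`` sets the depolarization level /
excitation threshold, and ``eps`` the time-scale separation.  Note that the
constant ``I`` enters the *slow* equation with a minus sign; this is the
form realised by the electronic circuit the model describes, not the more
common formulation with the drive added to du/dt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FHNParams",
    "UnitState",
    "eval_f",
    "eval_g",
    "fhn_field",
    "find_equilibria",
    "find_equilibrium",
    "jacobian",
    "NoEquilibriumError",
]


class NoEquilibriumError(ValueError):
    """Raised when no real equilibrium exists on either nullcline branch."""


def _check_finite(name: str, *values: float) -> None:
    for x in values:
        if not math.isfinite(x):
            raise ValueError(f"{name} must be finite, got {x!r}")


@dataclass(frozen=True)
class FHNParams:
    """Dimensionless parameter set of one FHN unit.

    Parameters
    ----------
    epsilon : float
        Time-scale ratio between the slow and fast variables (> 0).
    I : float
        Depolarization parameter; subtracted on dv/dt.
    alpha : float
        Recovery-nullcline slope for u < 0 (default 0.5).
    beta : float
        Recovery-nullcline slope for u >= 0 (default 2.0).
    """

    epsilon: float
    I: float
    alpha: float = 0.5
    beta: float = 2.0

    def __post_init__(self) -> None:
        _check_finite("FHNParams fields", self.epsilon, self.I, self.alpha, self.beta)
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


@dataclass(frozen=True)
class UnitState:
    """State (u, v) of one unit: fast voltage u and slow recovery v."""

    u: float
    v: float

    def __post_init__(self) -> None:
        _check_finite("UnitState fields", self.u, self.v)

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


def eval_f(u):
    """Cubic nonlinearity f(u) = u - u^3/3 (fast nullcline is v = f(u))."""
    arr = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("eval_f requires finite input")
    return u - u**3 / 3.0 if np.isscalar(u) else arr - arr**3 / 3.0


def eval_g(u, alpha: float, beta: float):
    """Piecewise-linear recovery input: alpha*u for u < 0, beta*u for u >= 0.

    Continuous at u = 0; only its derivative jumps there.
    """
    arr = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(arr)) and math.isfinite(alpha) and math.isfinite(beta)):
        raise ValueError("eval_g requires finite inputs")
    out = np.where(arr < 0, alpha * arr, beta * arr)
    return float(out) if np.isscalar(u) else out


def fhn_field(state: UnitState, p: FHNParams, drive: float = 0.0) -> tuple[float, float]:
    """Time derivatives (du/dt, dv/dt) of one unit.

    ``drive`` is the additive coupling/stimulus term on du/dt; 0 for an
    isolated unit.
    """
    _check_finite("drive", drive)
    u, v = state.u, state.v
    du = eval_f(u) - v + drive
    dv = p.epsilon * (eval_g(u, p.alpha, p.beta) - v) - p.I
    return (du, dv)


def jacobian(p: FHNParams, u: float) -> np.ndarray:
    """Jacobian of the vector field at a point with fast variable ``u``.

    Uses the one-sided slope g'(u) = alpha (u < 0) / beta (u >= 0); at the
    kink u = 0 the u >= 0 branch is taken, matching eval_g.
    """
    gp = p.alpha if u < 0 else p.beta
    return np.array([[1.0 - u * u, -1.0], [p.epsilon * gp, -p.epsilon]])


def _branch_roots(c1: float, c0: float) -> np.ndarray:
    """Real roots of u^3/3 + c1*u + c0 = 0."""
    roots = np.roots([1.0 / 3.0, 0.0, c1, c0])
    real = roots[np.abs(roots.imag) < 1e-9].real
    # polish with a couple of Newton steps on the exact cubic
    for _ in range(3):
        fval = real**3 / 3.0 + c1 * real + c0
        fp = real**2 + c1
        step = np.where(np.abs(fp) > 1e-14, fval / np.where(fp == 0, 1.0, fp), 0.0)
        real = real - step
    return np.unique(np.round(real, 12))


def find_equilibria(p: FHNParams, drive: float = 0.0) -> list[UnitState]:
    """All equilibria of the unit (optionally under a constant drive on du/dt).

    At an equilibrium v* = f(u*) + drive and v* = g(u*) - I/eps, so u* is a
    root of f(u) - g(u) + I/eps + drive = 0 on each linear branch of g:

        u >= 0:  u^3/3 + (beta - 1)  u - (I/eps + drive) = 0
        u <  0:  u^3/3 + (alpha - 1) u - (I/eps + drive) = 0

    Each branch is a depressed cubic solved in closed form; roots falling
    outside their branch's half-line are discarded.  Results are sorted by
    increasing u.
    """
    c0 = -(p.I / p.epsilon + drive)
    sols: list[float] = []
    for u in _branch_roots(p.beta - 1.0, c0):
        if u >= 0:
            sols.append(float(u))
    for u in _branch_roots(p.alpha - 1.0, c0):
        if u < 0:
            sols.append(float(u))
    if not sols:
        raise NoEquilibriumError(f"no real equilibrium for {p}")
    out = [UnitState(u, float(eval_f(u)) + drive) for u in sorted(set(sols))]
    # sanity: residual of the field must vanish at every returned point
    for st in out:
        du, dv = fhn_field(st, p, drive)
        if abs(du) > 1e-9 or abs(dv) > 1e-9:  # pragma: no cover - defensive
            raise RuntimeError(f"equilibrium residual too large at {st}: {(du, dv)}")
    return out


def find_equilibrium(p: FHNParams, select: str = "rightmost", drive: float = 0.0) -> UnitState:
    """One equilibrium of the unit.

    ``select`` picks among multiple equilibria: "rightmost" (largest u; the
    branch the depolarized circuit rests on) or "leftmost".
    """
    eqs = find_equilibria(p, drive)
    if select == "rightmost":
        return eqs[-1]
    if select == "leftmost":
        return eqs[0]
    raise ValueError(f"unknown selection rule {select!r}")
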