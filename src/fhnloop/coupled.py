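"""Closed-loop hybrid system: two FHN units coupled through attenuations k and d.

Unit 1 plays the artificial (electronic) generator, unit 2 the
biological-oscillator surrogate.  The forward path injects d*u1 into du2/dt
(stimulation); the feedback path injects k*u2 into du1/dt (recording).  With
both paths on the loop can act as an autogenerator: a closed circuit that
oscillates even though, depending on parameters, each unit alone would sit
at rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FHNParams, eval_f, eval_g, find_equilibrium
from .solver import SolverConfig, Trajectory, integrate

__all__ = [
    "CouplingConfig",
    "HybridState",
    "PulseTrain",
    "coupled_field",
    "simulate_hybrid",
    "open_loop_response",
    "DEFAULT_TRANSIENT_FRACTION",
]

#: Fraction of the horizon discarded before computing asymptotic metrics.
DEFAULT_TRANSIENT_FRACTION = 0.3


@dataclass(frozen=True)
class CouplingConfig:
    """Loop attenuations and path switches.

    k scales the biological signal u2 entering unit 1 (feedback path); d
    scales the artificial signal u1 entering unit 2 (forward path).  A
    disabled path contributes exactly zero whatever its coefficient.
    """

    k: float = 0.0223
    d: float = 0.087
    forward_on: bool = True
    feedback_on: bool = True

    def __post_init__(self) -> None:
        if self.k < 0 or self.d < 0:
            raise ValueError("attenuation coefficients must be >= 0")


@dataclass(frozen=True)
class HybridState:
    """Joint state (u1, v1, u2, v2) of the two-unit loop."""

    u1: float
    v1: float
    u2: float
    v2: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.u1, self.v1, self.u2, self.v2])):
            raise ValueError("HybridState fields must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u1, self.v1, self.u2, self.v2], dtype=float)


@dataclass(frozen=True)
class PulseTrain:
    """Rectangular additive pulses on du1/dt: onsets, common width and height."""

    onsets: tuple[float, ...]
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("pulse width must be > 0")

    def __call__(self, t: float) -> float:
        for t0 in self.onsets:
            if t0 <= t < t0 + self.width:
                return self.amplitude
        return 0.0


def coupled_field(
    state: HybridState, p1: FHNParams, p2: FHNParams, c: CouplingConfig
) -> tuple[float, float, float, float]:
    """Rates (du1, dv1, du2, dv2) of the coupled system.

    du1/dt = f(u1) - v1 + [feedback] k*u2
    dv1/dt = eps1 (g(u1) - v1) - I1
    du2/dt = f(u2) - v2 + [forward]  d*u1
    dv2/dt = eps2 (g(u2) - v2) - I2
    """
    u1, v1, u2, v2 = state.u1, state.v1, state.u2, state.v2
    du1 = eval_f(u1) - v1 + (c.k * u2 if c.feedback_on else 0.0)
    dv1 = p1.epsilon * (eval_g(u1, p1.alpha, p1.beta) - v1) - p1.I
    du2 = eval_f(u2) - v2 + (c.d * u1 if c.forward_on else 0.0)
    dv2 = p2.epsilon * (eval_g(u2, p2.alpha, p2.beta) - v2) - p2.I
    return (du1, dv1, du2, dv2)


def _rhs(p1: FHNParams, p2: FHNParams, c: CouplingConfig, stim=None):
    k_eff = c.k if c.feedback_on else 0.0
    d_eff = c.d if c.forward_on else 0.0
    e1, i1, a1, b1 = p1.epsilon, p1.I, p1.alpha, p1.beta
    e2, i2, a2, b2 = p2.epsilon, p2.I, p2.alpha, p2.beta

    def rhs(t, y):
        u1, v1, u2, v2 = y
        drive = stim(t) if stim is not None else 0.0
        return (
            u1 - u1**3 / 3.0 - v1 + k_eff * u2 + drive,
            e1 * ((a1 if u1 < 0 else b1) * u1 - v1) - i1,
            u2 - u2**3 / 3.0 - v2 + d_eff * u1,
            e2 * ((a2 if u2 < 0 else b2) * u2 - v2) - i2,
        )

    return rhs


def default_init(p1: FHNParams, p2: FHNParams) -> HybridState:
    """Both units at their own uncoupled (rightmost) equilibrium.

    Mirrors the experiment's starting condition: both generators at rest in
    their uncoupled operating point before the loop is closed.
    """
    e1 = find_equilibrium(p1)
    e2 = find_equilibrium(p2)
    return HybridState(e1.u, e1.v, e2.u, e2.v)


def simulate_hybrid(
    p1: FHNParams,
    p2: FHNParams,
    c: CouplingConfig,
    init: HybridState | None = None,
    cfg: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the closed-loop system; 4-variable trajectory.

    ``init`` defaults to the two uncoupled equilibria.
    """
    cfg = cfg or SolverConfig()
    if init is None:
        init = default_init(p1, p2)
    meta = {
        "system": "hybrid",
        "p1": dict(epsilon=p1.epsilon, I=p1.I, alpha=p1.alpha, beta=p1.beta),
        "p2": dict(epsilon=p2.epsilon, I=p2.I, alpha=p2.alpha, beta=p2.beta),
        "coupling": dict(k=c.k, d=c.d, forward_on=c.forward_on, feedback_on=c.feedback_on),
        "init": list(init.as_array()),
    }
    return integrate(_rhs(p1, p2, c), init.as_array(), cfg, meta=meta)


def open_loop_response(
    p1: FHNParams,
    p2: FHNParams,
    c: CouplingConfig,
    stim: PulseTrain | None,
    cfg: SolverConfig | None = None,
    init: HybridState | None = None,
) -> Trajectory:
    """Drive the open loop (feedback off) with an additive pulse train on du1/dt.

    Used to measure the stimulus-to-response delay on channel 2: with no
    communication loop the surrogate answers each pulse after a finite lag.
    """
    if c.feedback_on:
        c = CouplingConfig(c.k, c.d, forward_on=c.forward_on, feedback_on=False)
    cfg = cfg or SolverConfig()
    if init is None:
        # rest state of the *driven* open loop: unit 1 uncoupled, unit 2
        # shifted by the constant d*u1 it receives before any pulse arrives
        e1 = find_equilibrium(p1)
        e2 = find_equilibrium(p2, drive=(c.d * e1.u if c.forward_on else 0.0))
        init = HybridState(e1.u, e1.v, e2.u, e2.v)
    meta = {
        "system": "open_loop",
        "p1": dict(epsilon=p1.epsilon, I=p1.I, alpha=p1.alpha, beta=p1.beta),
        "p2": dict(epsilon=p2.epsilon, I=p2.I, alpha=p2.alpha, beta=p2.beta),
        "coupling": dict(k=c.k, d=c.d, forward_on=c.forward_on, feedback_on=c.feedback_on),
        "stim": None if stim is None else dict(onsets=list(stim.onsets), width=stim.width, amplitude=stim.amplitude),
    }
    return integrate(_rhs(p1, p2, c, stim), init.as_array(), cfg, meta=meta)


def single_unit_rhs(p: FHNParams):
    """RHS closure for one isolated unit (used for oracle comparisons)."""
    e, i, a, b = p.epsilon, p.I, p.alpha, p.beta

    def rhs(t, y):
        u, v = y
        return (u - u**3 / 3.0 - v, e * ((a if u < 0 else b) * u - v) - i)

    return rhs
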