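"""Regime classification, excitable/oscillatory boundary location, coupling sweeps.

A unit is called *oscillatory* when, started from its (rightmost)
equilibrium nudged by +0.1 on u, it keeps producing spikes after the
transient: at least ``SUSTAINED_SPIKES`` spikes in the final half of the
run.  This operational definition is deliberately simulation-based — near
the upper boundary the limit cycle shrinks below the detection thresholds,
and at low depolarization a stable rest state on the u < 0 branch can
coexist with large excursions, so linear stability of a single equilibrium
does not decide the matter on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coupled import CouplingConfig, simulate_hybrid, single_unit_rhs
from .model import FHNParams, find_equilibrium, jacobian
from .solver import SolverConfig, integrate
from .metrics import (
    DEFAULT_DOWN_THRESHOLD,
    DEFAULT_UP_THRESHOLD,
    calibrate_time,
    detect_spikes_channel,
    spike_stats,
)

__all__ = [
    "RegimeLabel",
    "FrequencyCurve",
    "ThresholdScanResult",
    "InvalidBracketError",
    "classify_regime",
    "threshold_scan",
    "oscillatory_window",
    "coupling_sweep",
    "unit_frequency",
    "frequency_over_window",
    "solve_attainable_frequency",
    "SUSTAINED_SPIKES",
    "CLASSIFY_PERTURBATION",
]

#: Minimum spike count in the final half-horizon to call a unit oscillatory.
SUSTAINED_SPIKES = 5
#: Perturbation applied to u at the equilibrium before classification.
CLASSIFY_PERTURBATION = 0.1


class InvalidBracketError(ValueError):
    """threshold_scan was given a bracket whose ends share a label."""


@dataclass(frozen=True)
class RegimeLabel:
    """Classification outcome plus the evidence that produced it."""

    label: str  # "excitable" | "oscillatory"
    evidence: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in ("excitable", "oscillatory"):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ThresholdScanResult:
    """Bisection result: boundary estimate and the final bracket."""

    i_star: float
    bracket: tuple[float, float]
    label_lo: str
    label_hi: str

    def __float__(self) -> float:
        return self.i_star


@dataclass
class FrequencyCurve:
    """Asymptotic channel-1 frequency versus a swept coupling coefficient.

    ``frequencies`` are calibrated to Hz when the sweep was run with a
    duration calibration, else dimensionless (1 / time unit).  A point where
    no sustained spiking occurred carries frequency 0; a point whose
    simulation failed carries the error message in ``errors``.
    """

    sweep_values: np.ndarray
    frequencies: np.ndarray
    spike_counts: np.ndarray
    labels: list[str]
    errors: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sweep_values = np.asarray(self.sweep_values, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.spike_counts = np.asarray(self.spike_counts, dtype=int)
        n = len(self.sweep_values)
        if not (len(self.frequencies) == len(self.spike_counts) == len(self.labels) == n):
            raise ValueError("sweep columns must align")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be >= 0")


def _default_cfg(horizon: float = 500.0) -> SolverConfig:
    return SolverConfig(horizon=horizon)


def classify_regime(p: FHNParams, cfg: SolverConfig | None = None) -> RegimeLabel:
    """Label one unit excitable or oscillatory by direct simulation.

    Integrates from the rightmost equilibrium perturbed by
    (+CLASSIFY_PERTURBATION, 0); the unit is oscillatory iff at least
    SUSTAINED_SPIKES spikes fall in the final half of the horizon.  The
    evidence record carries the spike count, the equilibrium, and the
    Jacobian eigenvalues there (one-sided slope of g at the kink).
    """
    cfg = cfg or _default_cfg()
    eq = find_equilibrium(p)
    traj = integrate(single_unit_rhs(p), [eq.u + CLASSIFY_PERTURBATION, eq.v], cfg)
    train = detect_spikes_channel(traj, 0, DEFAULT_UP_THRESHOLD, DEFAULT_DOWN_THRESHOLD)
    t_half = traj.times[0] + 0.5 * (traj.times[-1] - traj.times[0])
    n_late = int(np.sum(train.spike_times >= t_half))
    eigs = np.linalg.eigvals(jacobian(p, eq.u))
    label = "oscillatory" if n_late >= SUSTAINED_SPIKES else "excitable"
    return RegimeLabel(
        label,
        evidence={
            "spike_count": n_late,
            "spike_count_total": len(train),
            "equilibrium": (eq.u, eq.v),
            "eigenvalues": eigs,
            "leading_real_part": float(eigs.real.max()),
        },
    )


def threshold_scan(
    p_base: FHNParams,
    I_lo: float,
    I_hi: float,
    tol: float = 1e-4,
    cfg: SolverConfig | None = None,
) -> ThresholdScanResult:
    """Bisect the excitable/oscillatory boundary in the depolarization I.

    Requires differing labels at the bracket ends; refines until the bracket
    is narrower than ``tol`` and returns its midpoint.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    cfg = cfg or _default_cfg()

    def lab(I: float) -> str:
        return classify_regime(FHNParams(p_base.epsilon, I, p_base.alpha, p_base.beta), cfg).label

    lo, hi = float(I_lo), float(I_hi)
    lab_lo, lab_hi = lab(lo), lab(hi)
    if lab_lo == lab_hi:
        raise InvalidBracketError(
            f"both bracket ends classify as {lab_lo!r} (I = {lo}, {hi})"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if lab(mid) == lab_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdScanResult(0.5 * (lo + hi), (lo, hi), lab_lo, lab_hi)


def oscillatory_window(
    p_base: FHNParams,
    search: tuple[float, float, float] = (-0.05, 0.12, 0.35),
    tol: float = 1e-4,
    cfg: SolverConfig | None = None,
) -> tuple[float, float]:
    """(I_lo, I_hi) bounding the oscillatory window of a unit.

    ``search`` gives (below, inside, above): an I below the window, one
    inside it, and one above it; each boundary is then located by bisection.
    """
    below, inside, above = search
    lo = threshold_scan(p_base, below, inside, tol, cfg).i_star
    hi = threshold_scan(p_base, inside, above, tol, cfg).i_star
    return (lo, hi)


def coupling_sweep(
    p1: FHNParams,
    p2: FHNParams,
    c_base: CouplingConfig,
    d_values,
    cfg: SolverConfig | None = None,
    discard_fraction: float = 0.3,
    calibration_anchor_ms: float | None = 25.0,
) -> FrequencyCurve:
    """Sweep the forward attenuation d and record channel-1 spike frequency.

    The experiment's knob is the stimulus amplitude reaching the tissue; in
    the model that role is played by d, which scales the artificial signal
    entering the surrogate unit.  For each d the closed loop (both paths on)
    is simulated and the asymptotic channel-1 spike frequency recorded — 0
    when no sustained spiking survives the transient discard.

    With ``calibration_anchor_ms`` set (default 25 ms, the circuit's pulse
    duration) the frequency is reported in Hz under a per-point duration
    calibration, matching how the hardware frequency is read off in
    physical units; pass None for the raw dimensionless repetition rate.
    Per-point failures are recorded in ``errors`` without aborting the sweep.
    """
    d_values = np.asarray(d_values, dtype=float)
    if d_values.size == 0:
        raise ValueError("d_values must be non-empty")
    if np.any(d_values < 0) or np.any(np.diff(d_values) < 0):
        raise ValueError("d_values must be non-negative and sorted")
    cfg = cfg or _default_cfg()

    freqs = np.zeros(d_values.size)
    counts = np.zeros(d_values.size, dtype=int)
    labels: list[str] = []
    errors: dict[int, str] = {}
    for i, d in enumerate(d_values):
        c = CouplingConfig(k=c_base.k, d=float(d), forward_on=True, feedback_on=True)
        try:
            traj = simulate_hybrid(p1, p2, c, cfg=cfg)
            train = detect_spikes_channel(traj, 0, discard_fraction=discard_fraction)
            counts[i] = len(train)
            if len(train) >= max(3, SUSTAINED_SPIKES):
                stats = spike_stats(train)
                if calibration_anchor_ms is not None:
                    cal = calibrate_time(stats["mean_duration"], calibration_anchor_ms)
                    freqs[i] = cal.frequency_hz(stats["mean_period"])
                else:
                    freqs[i] = stats["frequency"]
                labels.append("oscillatory")
            else:
                labels.append("excitable")
        except Exception as exc:  # recorded per point, sweep continues
            errors[i] = f"{type(exc).__name__}: {exc}"
            labels.append("excitable")
    return FrequencyCurve(
        d_values, freqs, counts, labels, errors,
        meta={
            "k": c_base.k,
            "calibration_anchor_ms": calibration_anchor_ms,
            "discard_fraction": discard_fraction,
            "p1": dict(epsilon=p1.epsilon, I=p1.I, alpha=p1.alpha, beta=p1.beta),
            "p2": dict(epsilon=p2.epsilon, I=p2.I, alpha=p2.alpha, beta=p2.beta),
        },
    )


def unit_frequency(
    p: FHNParams,
    cfg: SolverConfig | None = None,
    discard_fraction: float = 0.3,
    calibration_anchor_ms: float | None = 25.0,
) -> float:
    """Asymptotic pulse repetition frequency of one unit, 0 if not spiking.

    With the default duration calibration the result is in Hz (the mean
    pulse duration is pinned to the anchor); with ``None`` it is the
    dimensionless repetition rate.
    """
    cfg = cfg or _default_cfg()
    eq = find_equilibrium(p)
    traj = integrate(single_unit_rhs(p), [eq.u + CLASSIFY_PERTURBATION, eq.v], cfg)
    train = detect_spikes_channel(traj, 0, discard_fraction=discard_fraction)
    if len(train) < max(3, SUSTAINED_SPIKES):
        return 0.0
    stats = spike_stats(train)
    if calibration_anchor_ms is None:
        return stats["frequency"]
    cal = calibrate_time(stats["mean_duration"], calibration_anchor_ms)
    return cal.frequency_hz(stats["mean_period"])


def frequency_over_window(
    p_base: FHNParams,
    window: tuple[float, float] | None = None,
    n_points: int = 13,
    cfg: SolverConfig | None = None,
    calibration_anchor_ms: float | None = 25.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated frequency versus I across the unit's oscillatory window.

    The grid is geometric in distance from the upper boundary (from the
    lower edge up to 0.1% of the window width below the upper edge): the
    pulse duty, and with it the calibrated frequency, varies fastest in the
    narrow canard band just below the boundary, so uniform grids miss the
    upper part of the attainable frequency range.
    """
    if window is None:
        window = oscillatory_window(p_base, cfg=cfg)
    lo, hi = window
    frac = 10.0 ** (-3.0 * np.arange(n_points)[::-1] / (n_points - 1))
    i_values = hi - (hi - lo) * frac
    freqs = np.array([
        unit_frequency(
            FHNParams(p_base.epsilon, float(I), p_base.alpha, p_base.beta),
            cfg, calibration_anchor_ms=calibration_anchor_ms,
        )
        for I in i_values
    ])
    return i_values, freqs


def solve_attainable_frequency(
    p_base: FHNParams,
    target_hz: float,
    window: tuple[float, float] | None = None,
    n_points: int = 13,
    cfg: SolverConfig | None = None,
    calibration_anchor_ms: float = 25.0,
    xtol: float = 1e-6,
) -> tuple[float, float]:
    """Find I in the oscillatory window whose calibrated frequency hits a target.

    Scans the window, brackets the target between adjacent grid points and
    refines by root finding on the simulated frequency curve.  Returns
    (I, simulated frequency at I).  Raises ValueError when the target lies
    outside the attainable set.
    """
    from scipy.optimize import brentq

    if window is None:
        window = oscillatory_window(p_base, cfg=cfg)
    i_values, freqs = frequency_over_window(
        p_base, window, n_points, cfg, calibration_anchor_ms
    )
    alive = freqs > 0
    sign = np.sign(freqs - target_hz)
    bracket = None
    for i in range(len(i_values) - 1):
        if alive[i] and alive[i + 1] and sign[i] * sign[i + 1] <= 0:
            bracket = (float(i_values[i]), float(i_values[i + 1]))
            break
    if bracket is None:
        raise ValueError(
            f"target {target_hz} Hz outside attainable range "
            f"[{freqs[alive].min():.2f}, {freqs[alive].max():.2f}] Hz"
        )

    def objective(I: float) -> float:
        return unit_frequency(
            FHNParams(p_base.epsilon, I, p_base.alpha, p_base.beta),
            cfg, calibration_anchor_ms=calibration_anchor_ms,
        ) - target_hz

    i_star = float(brentq(objective, *bracket, xtol=xtol))
    return i_star, objective(i_star) + target_hz
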