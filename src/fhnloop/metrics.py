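"""Spike detection, pulse statistics, time calibration and synchronization metrics.

Operates on uniformly sampled scalar signals (one trajectory channel or a
user-supplied two-column recording).  Spike detection uses hysteresis: a
spike opens on an upward crossing of ``up_threshold`` and closes on the next
downward crossing of ``down_threshold`` (< up), so noise riding on a pulse
cannot double-count it.  For dimensionless FHN signals the defaults are
up = +1.0 and down = 0.0: spikes peak near +2 and rest near -1, and the
pulse "duration" is the time the signal spends above the hysteresis floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import Trajectory

__all__ = [
    "SpikeTrain",
    "TimeCalibration",
    "SyncMetrics",
    "InsufficientSpikesError",
    "detect_spikes",
    "spike_stats",
    "calibrate_time",
    "sync_metrics",
    "phase_portrait",
    "DEFAULT_UP_THRESHOLD",
    "DEFAULT_DOWN_THRESHOLD",
]

DEFAULT_UP_THRESHOLD = 1.0
DEFAULT_DOWN_THRESHOLD = 0.0


class InsufficientSpikesError(ValueError):
    """Too few spikes for the requested statistic."""


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes on one channel: onset times, durations, peak values."""

    spike_times: np.ndarray
    durations: np.ndarray
    peaks: np.ndarray

    def __post_init__(self) -> None:
        for name in ("spike_times", "durations", "peaks"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.spike_times)
        if len(self.durations) != n or len(self.peaks) != n:
            raise ValueError("spike_times, durations and peaks must align")
        if n > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValueError("spike_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.spike_times)


@dataclass(frozen=True)
class TimeCalibration:
    """Physical-time scale: milliseconds per dimensionless time unit."""

    ms_per_unit: float

    def __post_init__(self) -> None:
        if not (self.ms_per_unit > 0):
            raise ValueError("ms_per_unit must be > 0")

    def to_ms(self, t_dimless):
        return np.asarray(t_dimless) * self.ms_per_unit

    def frequency_hz(self, period_dimless: float) -> float:
        """Pulse repetition frequency in Hz of a dimensionless period."""
        return 1000.0 / (period_dimless * self.ms_per_unit)


@dataclass(frozen=True)
class SyncMetrics:
    """Two-channel synchronization summary.

    plv is the phase-locking value computed with the spike-phase method:
    each channel-2 spike is assigned a phase by linear interpolation between
    the two surrounding channel-1 spikes, and plv is the modulus of the mean
    unit phasor of those phases (1 = perfect locking, ~n^-1/2 for
    independent trains).  lag is the circular mean phase expressed in time
    units of channel 1's mean period (channel 2 minus channel 1).
    """

    freq1: float
    freq2: float
    freq_ratio: float
    plv: float
    lag: float


def _interp_crossing(t0, t1, y0, y1, level):
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_spikes(
    times: np.ndarray,
    values: np.ndarray,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
) -> SpikeTrain:
    """Hysteresis threshold-crossing spike detection on a sampled signal.

    A spike opens at an upward crossing of ``up_threshold`` and closes at the
    next downward crossing of ``down_threshold``; its duration is the time
    the signal exceeds ``down_threshold`` within the spike, with both
    crossings located by linear interpolation between samples.  A spike
    still open at the end of the record is discarded (unknown duration).
    """
    if down_threshold >= up_threshold:
        raise ValueError("down_threshold must be below up_threshold")
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D and aligned")
    if len(t) < 2:
        raise ValueError("need at least 2 samples")

    onsets, durations, peaks = [], [], []
    in_spike = False
    t_open = t_floor = peak = 0.0
    for i in range(1, len(t)):
        if not in_spike:
            if y[i - 1] < up_threshold <= y[i]:
                in_spike = True
                t_open = _interp_crossing(t[i - 1], t[i], y[i - 1], y[i], up_threshold)
                # the signal crossed the hysteresis floor on its way up;
                # locate that earlier crossing inside the same rise
                j = i
                while j > 0 and y[j - 1] > down_threshold:
                    j -= 1
                if j > 0:
                    t_floor = _interp_crossing(t[j - 1], t[j], y[j - 1], y[j], down_threshold)
                else:
                    t_floor = t[0]
                peak = y[i]
        else:
            peak = max(peak, y[i])
            if y[i - 1] >= down_threshold > y[i]:
                t_close = _interp_crossing(t[i - 1], t[i], y[i - 1], y[i], down_threshold)
                onsets.append(t_open)
                durations.append(t_close - t_floor)
                peaks.append(peak)
                in_spike = False
    return SpikeTrain(np.array(onsets), np.array(durations), np.array(peaks))


def detect_spikes_channel(
    traj: Trajectory,
    channel: int = 0,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    discard_fraction: float = 0.0,
) -> SpikeTrain:
    """detect_spikes on one trajectory channel, optionally after transient discard."""
    t0 = traj.times[0] + discard_fraction * (traj.times[-1] - traj.times[0])
    sub = traj.after(t0)
    return detect_spikes(sub.times, sub.channel(channel), up_threshold, down_threshold)


def spike_stats(train: SpikeTrain) -> dict:
    """Mean period, mean duration and repetition frequency of a spike train.

    Requires >= 3 spikes so the period is averaged over >= 2 intervals.
    """
    if len(train) < 3:
        raise InsufficientSpikesError(f"need >= 3 spikes, got {len(train)}")
    periods = np.diff(train.spike_times)
    mean_period = float(np.mean(periods))
    return {
        "mean_period": mean_period,
        "mean_duration": float(np.mean(train.durations)),
        "frequency": 1.0 / mean_period,
    }


def calibrate_time(mean_duration_dimless: float, anchor_ms: float = 25.0) -> TimeCalibration:
    """Pin physical time to the model by matching mean pulse duration.

    The calibration sets ms_per_unit so that the observed mean dimensionless
    pulse duration corresponds to ``anchor_ms`` milliseconds (the circuit's
    pulse duration).  Whether the anchor refers to a single pulse width or a
    pulse-train envelope is a modelling choice surfaced via ``anchor_ms``.
    """
    if not (mean_duration_dimless > 0 and anchor_ms > 0):
        raise ValueError("duration and anchor must be > 0")
    return TimeCalibration(ms_per_unit=anchor_ms / mean_duration_dimless)


def _spike_phases(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Phase in [0, 1) of each channel-2 spike within the channel-1 cycle.

    Only channel-2 spikes falling strictly inside the span of channel-1
    spikes are used.
    """
    phases = []
    for s in t2:
        i = np.searchsorted(t1, s, side="right")
        if i == 0 or i == len(t1):
            continue
        phases.append((s - t1[i - 1]) / (t1[i] - t1[i - 1]))
    return np.asarray(phases)


def plv_from_spike_times(t1: np.ndarray, t2: np.ndarray) -> tuple[float, float]:
    """(plv, circular mean phase in [0, 1)) of t2 relative to the t1 cycle."""
    phases = _spike_phases(np.asarray(t1, float), np.asarray(t2, float))
    if len(phases) == 0:
        raise InsufficientSpikesError("no channel-2 spikes inside the channel-1 span")
    phasors = np.exp(2j * np.pi * phases)
    mean = np.mean(phasors)
    return float(np.abs(mean)), float(np.angle(mean) / (2 * np.pi) % 1.0)


def sync_metrics(
    traj: Trajectory,
    up_threshold: float = DEFAULT_UP_THRESHOLD,
    down_threshold: float = DEFAULT_DOWN_THRESHOLD,
    discard_fraction: float = 0.3,
) -> SyncMetrics:
    """Synchronization metrics of a 4-variable trajectory (channels u1, u2)."""
    if traj.n_vars != 4:
        raise ValueError("sync_metrics needs a 4-variable trajectory")
    tr1 = detect_spikes_channel(traj, 0, up_threshold, down_threshold, discard_fraction)
    tr2 = detect_spikes_channel(traj, 2, up_threshold, down_threshold, discard_fraction)
    s1, s2 = spike_stats(tr1), spike_stats(tr2)
    plv, mean_phase = plv_from_spike_times(tr1.spike_times, tr2.spike_times)
    # a lag just below one period is a small negative lag
    signed_phase = mean_phase if mean_phase <= 0.5 else mean_phase - 1.0
    return SyncMetrics(
        freq1=s1["frequency"],
        freq2=s2["frequency"],
        freq_ratio=s1["frequency"] / s2["frequency"],
        plv=plv,
        lag=signed_phase * s1["mean_period"],
    )


def phase_portrait(traj: Trajectory, x_channel: int, y_channel: int,
                   discard_fraction: float = 0.3) -> np.ndarray:
    """(x, y) sample pairs after transient discard, e.g. u1 vs u2 (columns 0, 2)."""
    if not (0 <= x_channel < traj.n_vars and 0 <= y_channel < traj.n_vars):
        raise ValueError("unknown channel")
    t0 = traj.times[0] + discard_fraction * (traj.times[-1] - traj.times[0])
    sub = traj.after(t0)
    return np.column_stack([sub.channel(x_channel), sub.channel(y_channel)])
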