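"""Synthetic local-field-potential surrogate and evoked-potential indicators.

Emulates the statistical shape of hippocampal-slice LFP recordings so the
whole analysis chain is testable without real data: stimulus-locked
spike-shaped deflections of 10-20 mV, additive white Gaussian noise, a
stimulation artifact at each stimulus time, and a fixed stimulus-to-response
delay.  Every generated recording carries its ground truth (which stimuli
evoked a response, where, how large) for end-to-end recovery tests.

The default evoked template rises *linearly* to its peak and decays
exponentially.  The two indicators measured on real recordings — onset-to-
peak amplitude and the slope of the linear rising phase — presume a linear
rise, and a linear-rise template gives both indicators an exact generating
truth (slope = amplitude / rise time).  A smooth biexponential template
(fast-rise/slow-decay difference of exponentials) is available via
``template="biexponential"`` when waveform realism matters more than
truth recovery.

None of the default amplitudes, noise levels or delays are measured values
from any particular recording; they are plausible placeholders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "LFPGenConfig",
    "LFPRecording",
    "EvokedPotentialMetrics",
    "NoResponseError",
    "generate_lfp",
    "lowpass_filter",
    "evoked_metrics",
    "classify_polarity",
    "mv_to_dimensionless",
    "dimensionless_to_mv",
]


class NoResponseError(RuntimeError):
    """The signal never left the baseline band inside the analysis window."""


@dataclass(frozen=True)
class LFPGenConfig:
    """Generator settings for one surrogate recording.

    spike_amplitude_mv
        (lo, hi) range of evoked-peak amplitudes; drawn uniformly per event.
        Default (10, 20) mV, the amplitude band of the emulated population
        spikes.
    spike_width_ms
        Total width of the evoked deflection.  The linear rise occupies
        30% of it; the exponential decay time constant is 35% of it.
    noise_sd_mv
        SD of the additive white Gaussian noise.
    artifact_amplitude_mv, artifact_polarity
        Stimulation-artifact size and shape ("biphasic" = +/- square lobes,
        or "positive" / "negative" single lobes, 1 ms total).
    response_delay_ms
        Stimulus-to-response-onset latency.
    response_probability
        Per-stimulus probability that a response is evoked.
    sample_rate_khz
        Sampling rate (kHz).
    seed
        Integer seed; the only source of randomness.
    """

    spike_amplitude_mv: tuple[float, float] = (10.0, 20.0)
    spike_width_ms: float = 5.0
    noise_sd_mv: float = 0.5
    artifact_amplitude_mv: float = 2.0
    artifact_polarity: str = "biphasic"
    response_delay_ms: float = 5.0
    response_probability: float = 1.0
    sample_rate_khz: float = 10.0
    seed: int = 0
    template: str = "linear_rise"

    def __post_init__(self) -> None:
        lo, hi = self.spike_amplitude_mv
        if not (lo <= hi):
            raise ValueError("spike_amplitude_mv must satisfy lo <= hi")
        if not (0.0 <= self.response_probability <= 1.0):
            raise ValueError("response_probability must lie in [0, 1]")
        if self.spike_width_ms <= 0 or self.sample_rate_khz <= 0:
            raise ValueError("spike_width_ms and sample_rate_khz must be > 0")
        if self.noise_sd_mv < 0 or self.response_delay_ms < 0:
            raise ValueError("noise_sd_mv and response_delay_ms must be >= 0")
        if self.artifact_polarity not in ("biphasic", "positive", "negative"):
            raise ValueError(f"unknown artifact_polarity {self.artifact_polarity!r}")
        if self.template not in ("linear_rise", "biexponential"):
            raise ValueError(f"unknown template {self.template!r}")


@dataclass
class LFPRecording:
    """A sampled surrogate recording in physical units (ms, mV)."""

    times_ms: np.ndarray
    voltage_mv: np.ndarray
    stim_times_ms: np.ndarray
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.voltage_mv = np.asarray(self.voltage_mv, dtype=float)
        self.stim_times_ms = np.asarray(self.stim_times_ms, dtype=float)
        if self.times_ms.shape != self.voltage_mv.shape:
            raise ValueError("times and voltages must align")
        if self.stim_times_ms.size and (
            self.stim_times_ms.min() < self.times_ms[0]
            or self.stim_times_ms.max() > self.times_ms[-1]
        ):
            raise ValueError("stimulus times must lie within the record")

    @property
    def sample_dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


@dataclass(frozen=True)
class EvokedPotentialMetrics:
    """Onset-to-peak amplitude and linear-rise slope of one evoked response."""

    amplitude_mv: float
    slope_mv_per_ms: float
    linear_start_ms: float
    linear_end_ms: float
    polarity: str
    onset_ms: float
    peak_ms: float

    def __post_init__(self) -> None:
        if not (self.linear_start_ms < self.linear_end_ms):
            raise ValueError("linear_start_ms must precede linear_end_ms")
        if self.polarity not in ("positive", "negative", "indeterminate"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.polarity == "positive" and self.amplitude_mv < 0:
            raise ValueError("positive polarity with negative amplitude")
        if self.polarity == "negative" and self.amplitude_mv > 0:
            raise ValueError("negative polarity with positive amplitude")


def _template_samples(cfg: LFPGenConfig, t_rel_ms: np.ndarray) -> np.ndarray:
    """Unit-peak evoked waveform evaluated at times since response onset."""
    w = cfg.spike_width_ms
    tt = np.maximum(t_rel_ms, 0.0)  # clamp so exp() cannot overflow pre-onset
    if cfg.template == "linear_rise":
        rise = 0.3 * w
        tau = 0.35 * w
        y = np.where(tt < rise, tt / rise, np.exp(-(np.maximum(tt - rise, 0.0)) / tau))
        return np.where(t_rel_ms >= 0, y, 0.0)
    # biexponential: fast rise, slower decay, renormalised to unit peak
    tau_r, tau_d = w / 8.0, w / 2.5
    t_peak = tau_r * tau_d / (tau_d - tau_r) * math.log(tau_d / tau_r)
    norm = math.exp(-t_peak / tau_d) - math.exp(-t_peak / tau_r)
    y = (np.exp(-tt / tau_d) - np.exp(-tt / tau_r)) / norm
    return np.where(t_rel_ms >= 0, y, 0.0)


def _truth_slope(cfg: LFPGenConfig, amplitude: float) -> float:
    """Slope of the template's rising phase, in mV/ms, at a given amplitude."""
    if cfg.template == "linear_rise":
        return amplitude / (0.3 * cfg.spike_width_ms)
    # steepest secant over the central 20-80% of the biexponential rise
    dt = 1e-3
    t = np.arange(0.0, cfg.spike_width_ms, dt)
    y = _template_samples(cfg, t) * amplitude
    i_pk = int(np.argmax(np.abs(y)))
    rise = y[: i_pk + 1]
    lo = int(np.searchsorted(rise, 0.2 * rise[-1]))
    hi = int(np.searchsorted(rise, 0.8 * rise[-1]))
    return (rise[hi] - rise[lo]) / ((hi - lo) * dt)


def _artifact(cfg: LFPGenConfig, t_rel_ms: np.ndarray) -> np.ndarray:
    """Stimulation artifact waveform, 1 ms total, at times since the stimulus."""
    a = cfg.artifact_amplitude_mv
    if cfg.artifact_polarity == "biphasic":
        return np.where(
            (t_rel_ms >= 0) & (t_rel_ms < 0.5), a,
            np.where((t_rel_ms >= 0.5) & (t_rel_ms < 1.0), -a, 0.0),
        )
    sign = 1.0 if cfg.artifact_polarity == "positive" else -1.0
    return np.where((t_rel_ms >= 0) & (t_rel_ms < 1.0), sign * a, 0.0)


def generate_lfp(
    cfg: LFPGenConfig,
    duration_ms: float,
    stim_times_ms=None,
) -> LFPRecording:
    """Generate one surrogate recording.

    For each stimulus time an artifact is placed at the stimulus, and with
    probability ``response_probability`` an evoked deflection is placed at
    stimulus + response_delay_ms with amplitude drawn uniformly from the
    configured range.  White Gaussian noise is added last.  Fully
    reproducible from ``cfg.seed``.

    ``stim_times_ms`` defaults to a regular train every 200 ms from 50 ms.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be > 0")
    if stim_times_ms is None:
        stim_times_ms = np.arange(50.0, duration_ms - 50.0, 200.0)
    stim_times_ms = np.asarray(stim_times_ms, dtype=float)

    dt = 1.0 / cfg.sample_rate_khz
    n = int(round(duration_ms / dt)) + 1
    t = np.arange(n) * dt
    v = np.zeros(n)
    rng = np.random.default_rng(cfg.seed)

    events = []
    lo, hi = cfg.spike_amplitude_mv
    for s in stim_times_ms:
        v += _artifact(cfg, t - s)
        responded = bool(rng.random() < cfg.response_probability)
        amp = float(rng.uniform(lo, hi))
        if responded:
            onset = s + cfg.response_delay_ms
            v += amp * _template_samples(cfg, t - onset)
            events.append({
                "stim_ms": float(s),
                "responded": True,
                "onset_ms": float(onset),
                "amplitude_mv": amp,
                "slope_mv_per_ms": _truth_slope(cfg, amp),
            })
        else:
            events.append({"stim_ms": float(s), "responded": False})
    if cfg.noise_sd_mv > 0:
        v = v + rng.normal(0.0, cfg.noise_sd_mv, n)

    meta = {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
    meta["spike_amplitude_mv"] = list(cfg.spike_amplitude_mv)
    return LFPRecording(t, v, stim_times_ms, truth={"events": events}, meta=meta)


def lowpass_filter(rec: LFPRecording, cutoff_hz: float, order: int = 4) -> LFPRecording:
    """Zero-phase Butterworth low-pass; DC gain exactly 1.

    ``cutoff_hz`` must lie below the Nyquist frequency of the recording.
    """
    fs_hz = 1000.0 / rec.sample_dt_ms
    if not (0 < cutoff_hz < fs_hz / 2):
        raise ValueError(f"cutoff must lie in (0, {fs_hz / 2:.1f}) Hz")
    b, a = butter(order, cutoff_hz, fs=fs_hz)
    filtered = filtfilt(b, a, rec.voltage_mv)
    meta = dict(rec.meta)
    meta["lowpass_cutoff_hz"] = float(cutoff_hz)
    meta["lowpass_order"] = int(order)
    return LFPRecording(rec.times_ms.copy(), filtered, rec.stim_times_ms.copy(),
                        truth=rec.truth, meta=meta)


def _baseline_band(rec: LFPRecording, stim_time_ms: float, baseline_ms: float,
                   sd_floor: float = 1e-9) -> tuple[float, float]:
    mask = (rec.times_ms >= stim_time_ms - baseline_ms) & (rec.times_ms < stim_time_ms)
    if mask.sum() < 2:
        raise ValueError("not enough pre-stimulus samples for a baseline estimate")
    seg = rec.voltage_mv[mask]
    return float(np.mean(seg)), max(float(np.std(seg)), sd_floor)


def _analysis_window(rec, stim_time_ms, window_ms, blanking_ms):
    if stim_time_ms + window_ms > rec.times_ms[-1] + 1e-9:
        raise ValueError("analysis window extends past the end of the record")
    mask = (rec.times_ms > stim_time_ms + blanking_ms) & (
        rec.times_ms <= stim_time_ms + window_ms
    )
    return np.where(mask)[0]


def _find_onset(y, band_lo, band_hi, run: int):
    outside = (y < band_lo) | (y > band_hi)
    count = 0
    for i, out in enumerate(outside):
        count = count + 1 if out else 0
        if count >= run:
            return i - run + 1
    return None


def evoked_metrics(
    rec: LFPRecording,
    stim_time_ms: float,
    window_ms: float,
    blanking_ms: float = 2.0,
    baseline_ms: float = 20.0,
    onset_run_ms: float = 0.5,
    linearity_window: int = 5,
    r2_min: float = 0.98,
) -> EvokedPotentialMetrics:
    """Onset-to-peak amplitude and linear-rise slope of one evoked response.

    Onset is the first post-blanking sample where the signal leaves the
    baseline band (pre-stimulus mean +/- 3 SD) and stays out for
    ``onset_run_ms``; the sustained-run requirement keeps isolated noise
    samples from declaring a response.  Amplitude is the extremum value
    minus the onset value.  The linear region is the longest run of
    ``linearity_window``-sample windows between onset and peak whose local
    straight-line fit explains at least ``r2_min`` of the local variance;
    the slope is the straight-line fit over that run.  The first
    ``blanking_ms`` after the stimulus are excluded so the stimulation
    artifact cannot masquerade as the response.

    Raises :class:`NoResponseError` if the signal never leaves the band.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    base_mean, base_sd = _baseline_band(rec, stim_time_ms, baseline_ms)
    idx = _analysis_window(rec, stim_time_ms, window_ms, blanking_ms)
    y = rec.voltage_mv[idx]
    t = rec.times_ms[idx]
    dt = rec.sample_dt_ms
    run = max(2, int(round(onset_run_ms / dt)))
    i_out = _find_onset(y, base_mean - 3 * base_sd, base_mean + 3 * base_sd, run)
    if i_out is None:
        raise NoResponseError(
            f"no baseline exit within {window_ms} ms of stimulus at {stim_time_ms} ms"
        )
    # onset = the departure sample: the last sample still inside the band
    i_on = max(i_out - 1, 0)
    seg = y[i_on:]
    i_pk = i_on + int(np.argmax(np.abs(seg - base_mean)))
    amplitude = float(y[i_pk] - y[i_on])
    deflection = float(y[i_pk] - base_mean)
    polarity = _polarity_of_extrema(y, base_mean)

    # linear region between onset and peak: longest run of qualifying local
    # windows, provided it spans a substantial part of the rise — a short
    # by-chance run on noisy data is not "the linear phase", so anything
    # covering less than a third of the rise falls back to the full rise
    a, b = sorted((i_on, i_pk))
    rise_t, rise_y = t[a : b + 1], y[a : b + 1]
    w = linearity_window
    if len(rise_y) <= w:
        start, stop = 0, len(rise_y) - 1
    else:
        ok = np.zeros(len(rise_y) - w + 1, dtype=bool)
        for j in range(len(ok)):
            ok[j] = _local_r2(rise_t[j : j + w], rise_y[j : j + w]) >= r2_min
        start, stop = _longest_true_run(ok)
        if start is None or (stop + w - start) < max(2 * w, len(rise_y) // 3):
            start, stop = 0, len(rise_y) - 1
        else:
            stop = stop + w - 1  # last window's final sample
    slope = float(np.polyfit(rise_t[start : stop + 1], rise_y[start : stop + 1], 1)[0])
    return EvokedPotentialMetrics(
        amplitude_mv=amplitude,
        slope_mv_per_ms=slope,
        linear_start_ms=float(rise_t[start]),
        linear_end_ms=float(rise_t[stop]),
        polarity=polarity,
        onset_ms=float(t[i_on]),
        peak_ms=float(t[i_pk]),
    )


def _local_r2(t, y) -> float:
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    coeffs = np.polyfit(t, y, 1)
    resid = y - np.polyval(coeffs, t)
    ss_res = float(np.sum(resid**2))
    if ss_tot < 1e-24:
        return 1.0 if ss_res < 1e-24 else 0.0
    return 1.0 - ss_res / ss_tot


def _longest_true_run(mask):
    best_start, best_len = None, 0
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_start is None:
        return None, None
    return best_start, best_start + best_len - 1


def _polarity_of_extrema(y, base_mean, tie_fraction: float = 0.10) -> str:
    up = float(np.max(y) - base_mean)
    down = float(base_mean - np.min(y))
    big, small = max(up, down), min(up, down)
    if big <= 0:
        return "indeterminate"
    if (big - small) / big < tie_fraction:
        return "indeterminate"
    return "positive" if up > down else "negative"


def classify_polarity(
    rec: LFPRecording,
    stim_time_ms: float,
    window_ms: float,
    blanking_ms: float = 2.0,
    baseline_ms: float = 20.0,
) -> str:
    """Polarity of the dominant post-artifact deflection.

    "positive" if the dominant extremum is a maximum, "negative" if a
    minimum, "indeterminate" when the two deflections differ by < 10%.
    """
    base_mean, _ = _baseline_band(rec, stim_time_ms, baseline_ms)
    idx = _analysis_window(rec, stim_time_ms, window_ms, blanking_ms)
    return _polarity_of_extrema(rec.voltage_mv[idx], base_mean)


def mv_to_dimensionless(voltage_mv, scale: float):
    """Map millivolts to the dimensionless FHN voltage: u = voltage / scale."""
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    return np.asarray(voltage_mv) / scale if np.ndim(voltage_mv) else voltage_mv / scale


def dimensionless_to_mv(u, scale: float):
    """Inverse of :func:`mv_to_dimensionless`; round-trips exactly."""
    if not (scale > 0):
        raise ValueError("scale must be > 0")
    return np.asarray(u) * scale if np.ndim(u) else u * scale
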