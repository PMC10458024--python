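"""Spike detection, pulse statistics, calibration and synchronization."""

import numpy as np
import pytest

from fhnloop import (
    InsufficientSpikesError,
    SpikeTrain,
    Trajectory,
    calibrate_time,
    detect_spikes,
    phase_portrait,
    spike_stats,
    sync_metrics,
)
from fhnloop.metrics import plv_from_spike_times


def triangle_train(n_pulses=7, height=2.0, period=10.0, width=2.0, dt=0.01):
    """n identical triangular pulses rising from a -1 baseline."""
    t = np.arange(0.0, n_pulses * period, dt)
    y = np.full_like(t, -1.0)
    for k in range(n_pulses):
        onset = k * period + 2.0
        ramp = (t - onset) / (width / 2)
        up = -1.0 + (height + 1.0) * ramp
        down = -1.0 + (height + 1.0) * (2 - ramp)
        pulse = np.minimum(up, down)
        y = np.maximum(y, pulse)
    return t, y


class TestDetection:
    def test_constant_series_has_no_spikes(self):
        t = np.linspace(0, 10, 101)
        train = detect_spikes(t, np.zeros_like(t) + 0.4, 1.0, 0.0)
        assert len(train) == 0

    def test_seven_identical_triangles(self):
        t, y = triangle_train()
        train = detect_spikes(t, y, 1.0, 0.0)
        assert len(train) == 7
        assert np.ptp(train.durations) < 1e-9
        assert np.allclose(train.peaks, 2.0, atol=0.02)

    def test_noise_does_not_change_the_count(self, rng):
        t, y = triangle_train(height=2.0)
        noisy = y + rng.normal(0.0, 0.2, y.size)  # SD = 10% of pulse height
        clean = detect_spikes(t, y, 1.0, 0.4)  # 50% / 20% of height
        train = detect_spikes(t, noisy, 1.0, 0.4)
        assert len(train) == len(clean) == 7

    def test_offset_invariance(self):
        t, y = triangle_train()
        base = detect_spikes(t, y, 1.0, 0.0)
        shifted = detect_spikes(t, y + 3.7, 1.0 + 3.7, 0.0 + 3.7)
        assert np.allclose(base.spike_times, shifted.spike_times, atol=1e-9)
        assert np.allclose(base.durations, shifted.durations, atol=1e-9)

    def test_duration_is_time_above_hysteresis_floor(self):
        # one symmetric triangle: time above the floor is computable exactly
        t, y = triangle_train(n_pulses=1, height=2.0, width=2.0)
        train = detect_spikes(t, y, 1.0, 0.0)
        # rises 3 units over 1 time unit; above 0 for (2/3) * 2 = 4/3
        assert train.durations[0] == pytest.approx(4.0 / 3.0, abs=1e-2)

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            detect_spikes(np.array([0.0]), np.array([0.0]), 1.0, 0.0)
        with pytest.raises(ValueError):
            detect_spikes(np.arange(3.0), np.zeros(3), 0.0, 1.0)


class TestSpikeStats:
    def test_regular_train(self):
        train = SpikeTrain([0.0, 10.0, 20.0, 30.0], np.ones(4), np.ones(4))
        stats = spike_stats(train)
        assert stats["mean_period"] == pytest.approx(10.0)
        assert stats["frequency"] == pytest.approx(0.1)

    def test_irregular_train_uses_arithmetic_mean(self):
        train = SpikeTrain([0.0, 9.0, 21.0, 30.0], np.ones(4), np.ones(4))
        assert spike_stats(train)["mean_period"] == pytest.approx(10.0)

    def test_too_few_spikes(self):
        with pytest.raises(InsufficientSpikesError):
            spike_stats(SpikeTrain([0.0, 1.0], [0.1, 0.1], [1.0, 1.0]))


class TestCalibration:
    def test_anchor_sets_scale(self):
        assert calibrate_time(5.0, 25.0).ms_per_unit == pytest.approx(5.0)

    def test_frequency_conversion_units(self):
        # physical frequency of period P is 1000 * D / (anchor * P) Hz
        cal = calibrate_time(10.0, 25.0)
        assert cal.frequency_hz(18.0) == pytest.approx(1000.0 * 10.0 / (25.0 * 18.0))

    def test_doubling_anchor_halves_frequencies(self):
        f1 = calibrate_time(10.0, 25.0).frequency_hz(18.0)
        f2 = calibrate_time(10.0, 50.0).frequency_hz(18.0)
        assert f1 == pytest.approx(2.0 * f2)

    @pytest.mark.parametrize("dur, anchor", [(0.0, 25.0), (5.0, -1.0)])
    def test_invalid_inputs(self, dur, anchor):
        with pytest.raises(ValueError):
            calibrate_time(dur, anchor)


def _two_channel_traj(shift=0.0, n_pulses=30, period=10.0, dt=0.01):
    t, y1 = triangle_train(n_pulses=n_pulses, period=period, dt=dt)
    _, y2 = triangle_train(n_pulses=n_pulses, period=period, dt=dt)
    if shift:
        k = int(round(shift / dt))
        y2 = np.roll(y2, k)
        y2[:k] = -1.0
    states = np.column_stack([y1, np.zeros_like(y1), y2, np.zeros_like(y2)])
    return Trajectory(t, states)


class TestSync:
    def test_identical_channels_lock_perfectly(self):
        sm = sync_metrics(_two_channel_traj(0.0), discard_fraction=0.0)
        assert sm.plv == pytest.approx(1.0, abs=1e-12)
        assert sm.freq_ratio == pytest.approx(1.0, abs=1e-9)
        assert sm.lag == pytest.approx(0.0, abs=1e-6)

    def test_shifted_copy_keeps_plv_one_with_lag(self):
        sm = sync_metrics(_two_channel_traj(2.5), discard_fraction=0.0)
        assert sm.plv == pytest.approx(1.0, abs=1e-9)
        assert sm.lag == pytest.approx(2.5, abs=1e-2)

    def test_independent_trains_have_low_plv(self, rng):
        t1 = np.cumsum(rng.uniform(0.5, 1.5, size=200))
        t2 = np.cumsum(rng.uniform(0.5, 1.5, size=200))
        plv, _ = plv_from_spike_times(t1, t2)
        assert 0.0 <= plv < 0.2

    def test_plv_bounded_and_shift_invariant(self, rng):
        t1 = np.cumsum(rng.uniform(0.5, 1.5, size=50))
        t2 = np.cumsum(rng.uniform(0.5, 1.5, size=50))
        plv, phase = plv_from_spike_times(t1, t2)
        assert 0.0 <= plv <= 1.0
        plv_shifted, phase_shifted = plv_from_spike_times(t1 + 7.3, t2 + 7.3)
        assert plv_shifted == pytest.approx(plv, abs=1e-9)
        assert phase_shifted == pytest.approx(phase, abs=1e-9)

    def test_needs_four_variables(self):
        t = np.linspace(0, 10, 100)
        with pytest.raises(ValueError):
            sync_metrics(Trajectory(t, np.zeros((100, 2))))


class TestPhasePortrait:
    def test_fixed_point_collapses_to_a_dot(self):
        t = np.linspace(0, 10, 100)
        states = np.tile([0.5, -0.2, 0.1, 0.3], (100, 1))
        pts = phase_portrait(Trajectory(t, states), 0, 2)
        assert np.abs(pts - pts[0]).max() < 1e-6

    def test_length_matches_retained_samples(self):
        traj = _two_channel_traj(0.0)
        pts = phase_portrait(traj, 0, 2, discard_fraction=0.3)
        retained = np.sum(traj.times >= traj.times[0] + 0.3 * (traj.times[-1] - traj.times[0]))
        assert pts.shape == (retained, 2)

    def test_unknown_channel_rejected(self):
        traj = _two_channel_traj(0.0)
        with pytest.raises(ValueError):
            phase_portrait(traj, 0, 7)

    def test_locked_loop_orbit_closes(self, closed_loop_traj):
        # at the printed couplings the (u1, u2) orbit is a closed curve:
        # the final point must come back near an earlier cycle's point
        pts = phase_portrait(closed_loop_traj, 0, 2, discard_fraction=0.3)
        diam = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        last = pts[-1]
        earlier = pts[: len(pts) // 2]
        dist = np.linalg.norm(earlier - last, axis=1).min()
        assert dist < 0.05 * diam
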