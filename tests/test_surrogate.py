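"""Surrogate LFP generation, filtering and evoked-potential indicators."""

import numpy as np
import pytest

from fhnloop import (
    LFPGenConfig,
    LFPRecording,
    NoResponseError,
    classify_polarity,
    dimensionless_to_mv,
    evoked_metrics,
    generate_lfp,
    lowpass_filter,
    mv_to_dimensionless,
)

NOISELESS = LFPGenConfig(noise_sd_mv=0.0, response_probability=1.0, seed=7)


def make_recording(y, dt_ms=0.1, stim_ms=(50.0,)):
    t = np.arange(len(y)) * dt_ms
    return LFPRecording(t, np.asarray(y, float), np.asarray(stim_ms))


class TestGenerate:
    def test_bit_reproducible_from_seed(self):
        cfg = LFPGenConfig(seed=11)
        a = generate_lfp(cfg, 600.0)
        b = generate_lfp(cfg, 600.0)
        assert np.array_equal(a.voltage_mv, b.voltage_mv)
        assert a.truth == b.truth

    def test_evoked_amplitudes_stay_in_configured_band(self):
        rec = generate_lfp(NOISELESS, 2000.0)
        events = [e for e in rec.truth["events"] if e["responded"]]
        assert len(events) == len(rec.stim_times_ms)
        for e in events:
            assert 10.0 <= e["amplitude_mv"] <= 20.0
            m = evoked_metrics(rec, e["stim_ms"], 40.0)
            assert 10.0 <= m.amplitude_mv <= 20.0

    def test_noise_only_sample_sd(self):
        cfg = LFPGenConfig(noise_sd_mv=1.5, seed=3)
        rec = generate_lfp(cfg, 1e4, stim_times_ms=[])  # 1e5 samples at 10 kHz
        assert rec.voltage_mv.size >= 1e5
        assert np.std(rec.voltage_mv) == pytest.approx(1.5, rel=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LFPGenConfig(spike_amplitude_mv=(20.0, 10.0))
        with pytest.raises(ValueError):
            LFPGenConfig(response_probability=1.5)
        with pytest.raises(ValueError):
            LFPGenConfig(artifact_polarity="sideways")


class TestLowpass:
    def test_constant_signal_unchanged(self):
        rec = make_recording(np.full(2000, 3.3), stim_ms=())
        out = lowpass_filter(rec, 100.0)
        assert np.allclose(out.voltage_mv, 3.3, atol=1e-9)

    def test_sinusoid_above_cutoff_attenuated(self):
        dt = 0.1  # ms -> fs = 10 kHz
        t = np.arange(0, 500, dt)
        y = np.sin(2 * np.pi * 400.0 * t / 1000.0)  # 400 Hz, 4x cutoff
        out = lowpass_filter(make_recording(y, dt, ()), 100.0)
        mid = slice(1000, -1000)  # ignore edge transients
        assert np.abs(out.voltage_mv[mid]).max() < 0.1 * np.abs(y[mid]).max()

    def test_white_noise_loses_variance(self, rng):
        y = rng.normal(0, 1, 5000)
        out = lowpass_filter(make_recording(y, 0.1, ()), 500.0)
        assert np.var(out.voltage_mv) < np.var(y)

    def test_cutoff_must_be_below_nyquist(self):
        rec = make_recording(np.zeros(100), 0.1, ())
        with pytest.raises(ValueError):
            lowpass_filter(rec, 5000.0)


class TestEvokedMetrics:
    def ramp_recording(self, noise_sd=0.0, seed=0):
        # baseline 0; linear rise 2 mV/ms for 5 ms to 10 mV; exponential tail
        dt = 0.1
        t = np.arange(0, 120, dt)
        y = np.zeros_like(t)
        onset, rise = 55.0, 5.0
        mask = t >= onset
        y[mask] = np.where(
            t[mask] < onset + rise,
            2.0 * (t[mask] - onset),
            10.0 * np.exp(-(t[mask] - onset - rise) / 4.0),
        )
        if noise_sd:
            y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
        return make_recording(y, dt, (50.0,))

    def test_noiseless_ramp_recovered_exactly(self):
        m = evoked_metrics(self.ramp_recording(), 50.0, 40.0)
        assert m.amplitude_mv == pytest.approx(10.0, rel=1e-6)
        assert m.slope_mv_per_ms == pytest.approx(2.0, rel=0.01)
        assert m.polarity == "positive"
        assert m.onset_ms == pytest.approx(55.0, abs=0.1)

    def test_noisy_ramp_slope_within_five_percent(self):
        m = evoked_metrics(self.ramp_recording(noise_sd=0.2, seed=42), 50.0, 40.0)
        assert m.slope_mv_per_ms == pytest.approx(2.0, rel=0.05)

    def test_flat_recording_raises_no_response(self):
        rec = make_recording(np.zeros(1200), 0.1, (50.0,))
        with pytest.raises(NoResponseError):
            evoked_metrics(rec, 50.0, 40.0)

    def test_generator_truth_recovered_noiselessly(self):
        rec = generate_lfp(NOISELESS, 800.0)
        for e in rec.truth["events"]:
            m = evoked_metrics(rec, e["stim_ms"], 40.0)
            assert m.amplitude_mv == pytest.approx(e["amplitude_mv"], rel=0.01)
            assert m.slope_mv_per_ms == pytest.approx(e["slope_mv_per_ms"], rel=0.01)
            assert abs(m.onset_ms - e["onset_ms"]) <= rec.sample_dt_ms + 1e-9

    def test_biexponential_template_amplitude_recovered(self):
        cfg = LFPGenConfig(noise_sd_mv=0.0, template="biexponential", seed=5)
        rec = generate_lfp(cfg, 400.0)
        e = rec.truth["events"][0]
        m = evoked_metrics(rec, e["stim_ms"], 40.0)
        assert m.amplitude_mv == pytest.approx(e["amplitude_mv"], rel=0.01)


class TestPolarity:
    def test_upward_response_is_positive(self):
        rec = generate_lfp(NOISELESS, 400.0)
        assert classify_polarity(rec, rec.stim_times_ms[0], 40.0) == "positive"

    def test_inverted_response_is_negative(self):
        rec = generate_lfp(NOISELESS, 400.0)
        flipped = LFPRecording(
            rec.times_ms, -rec.voltage_mv, rec.stim_times_ms, rec.truth, rec.meta
        )
        assert classify_polarity(flipped, rec.stim_times_ms[0], 40.0) == "negative"

    def test_symmetric_signal_is_indeterminate(self):
        dt = 0.1
        t = np.arange(0, 120, dt)
        y = np.zeros_like(t)
        mask = (t >= 55) & (t < 65)
        y[mask] = 5.0 * np.sin(2 * np.pi * (t[mask] - 55) / 10.0)  # one full cycle
        rec = make_recording(y, dt, (50.0,))
        assert classify_polarity(rec, 50.0, 40.0) == "indeterminate"


class TestVoltageBridge:
    def test_simple_ratio(self):
        assert mv_to_dimensionless(15.0, 15.0) == pytest.approx(1.0)

    def test_round_trip(self, rng):
        vals = rng.uniform(-30, 30, 100)
        back = dimensionless_to_mv(mv_to_dimensionless(vals, 7.5), 7.5)
        assert np.allclose(back, vals, rtol=1e-12)

    def test_spike_band_maps_onto_fhn_peak_range(self):
        # scale chosen so a 15 mV spike maps to u = 2 (the FHN peak)
        scale = 15.0 / 2.0
        lo, hi = mv_to_dimensionless(10.0, scale), mv_to_dimensionless(20.0, scale)
        assert lo == pytest.approx(4.0 / 3.0)
        assert hi == pytest.approx(8.0 / 3.0)

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            mv_to_dimensionless(1.0, 0.0)
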