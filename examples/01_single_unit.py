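"""One FHN unit: equilibrium, regime, spike shape and calibrated frequency.

Simulates the electronic-generator unit at its circuit parameter set
(eps = 0.18, I = 0.19, alpha = 0.5, beta = 2), detects spikes with the
hysteresis thresholds (+1.0 up, 0.0 down) and pins physical time by setting
the mean pulse duration to 25 ms.
"""

from fhnloop import FHNParams, SolverConfig, classify_regime, find_equilibrium, integrate
from fhnloop.coupled import single_unit_rhs
from fhnloop.metrics import calibrate_time, detect_spikes_channel, spike_stats

p = FHNParams(epsilon=0.18, I=0.19, alpha=0.5, beta=2.0)
eq = find_equilibrium(p)
print(f"equilibrium: u* = {eq.u:.6f}, v* = {eq.v:.6f}")

label = classify_regime(p)
print(f"regime: {label.label} "
      f"(leading eigenvalue real part {label.evidence['leading_real_part']:+.4f})")

cfg = SolverConfig(horizon=500.0, sample_dt=0.01)
traj = integrate(single_unit_rhs(p), [eq.u + 0.1, eq.v], cfg)
train = detect_spikes_channel(traj, 0, discard_fraction=0.3)
stats = spike_stats(train)
cal = calibrate_time(stats["mean_duration"], anchor_ms=25.0)
print(f"{len(train)} spikes after transient; "
      f"mean period {stats['mean_period']:.3f}, mean duration {stats['mean_duration']:.3f} "
      f"(dimensionless time units)")
print(f"with 25 ms pulses this is {cal.frequency_hz(stats['mean_period']):.2f} Hz "
      f"({cal.ms_per_unit:.3f} ms per time unit)")
# The unit self-oscillates at this I: the rest state is an unstable focus,
# so the circuit emits a sustained pulse train rather than single spikes.
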