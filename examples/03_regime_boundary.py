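"""Locate the excitable/oscillatory boundary in I and hit 33 Hz.

Bisects the regime boundary of the eps = 0.18 unit, sweeps the
depolarization I across the oscillatory window, and solves for the I whose
duration-calibrated pulse frequency equals the circuit's 33 Hz operating
point.  Takes about a minute.
"""

from fhnloop import FHNParams, SolverConfig, threshold_scan
from fhnloop.regimes import frequency_over_window, solve_attainable_frequency

base = FHNParams(epsilon=0.18, I=0.0)
cfg = SolverConfig(horizon=500.0, sample_dt=0.01)

lo = threshold_scan(base, -0.05, 0.12, tol=1e-4, cfg=cfg)
hi = threshold_scan(base, 0.12, 0.35, tol=1e-4, cfg=cfg)
print(f"oscillatory window: I in ({lo.i_star:.5f}, {hi.i_star:.5f})")
print("below the window a stable rest state coexists with the left branch;")
print("above it the limit cycle collapses at a Hopf point near I = 0.2075")

window = (lo.i_star, hi.i_star)
i_values, freqs = frequency_over_window(base, window=window, cfg=cfg)
for i_val, f in zip(i_values, freqs):
    print(f"  I = {i_val:.5f}  ->  {f:6.2f} Hz (25 ms pulse-duration calibration)")

i_star, f_star = solve_attainable_frequency(base, 33.0, window=window, cfg=cfg)
print(f"33 Hz is attained at I = {i_star:.6f} (simulated frequency {f_star:.3f} Hz)")
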