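# Methods

## Model

Each unit is the dimensionless FitzHugh–Nagumo system

    du/dt = f(u) − v + drive,   f(u) = u − u³/3
    dv/dt = ε (g(u) − v) − I,   g(u) = αu (u < 0),  βu (u ≥ 0)

The constant `I` is subtracted on the **slow** equation.  This is the form
realised by the electronic circuit the package models, and it changes the
phenomenology relative to the textbook FHN (where the drive is added to
du/dt): raising `I` moves the rest point up the u ≥ 0 branch and
*stabilises* it, so the oscillatory regime occupies an interior window of
`I` rather than a half-line.  The recovery nullcline `g` is continuous with
a slope jump at u = 0; no event detection is used for it — the integrator's
error control handles the kink, with a step ceiling of 0.05 (and a
fixed-step RK4 oracle bounding the error in tests).

Two units are coupled resistively: `k·u₂` is added to du₁/dt (feedback,
recording side) and `d·u₁` to du₂/dt (forward, stimulation side).  Each
path has an on/off switch; a disabled path contributes exactly zero.  The
loop amplifier is not modelled separately — its gain is folded into `d`,
since the hardware only rescales the pulse amplitude.

### Equilibria

Setting both rates to zero gives `v = f(u) + drive` and
`v = g(u) − I/ε`, hence a depressed cubic per branch of `g`:

    u ≥ 0:  u³/3 + (β−1)u − (I/ε + drive) = 0
    u <  0: u³/3 + (α−1)u − (I/ε + drive) = 0

Both cubics are solved in closed form (with a Newton polish) and roots
outside their branch's half-line are discarded.  For α < 1 and small
positive `I` the u < 0 branch contributes **two extra equilibria**, one of
which is stable: at ε = 0.18, α = 0.5, β = 2 a stable rest state coexists
on the left branch for 0 < I ≲ 0.037.  Linear stability of a single
equilibrium therefore does not decide the regime at low `I`, which is why
classification is simulation-based (below).  Callers selecting a single
equilibrium get the *rightmost* one by default — the depolarized operating
point of the circuit.

### Stability structure at the reference parameters

At ε = 0.18, α = 0.5, β = 2 the rest point satisfies trace zero
(`f'(u*) = ε`) at I ≈ 0.2075 on the u ≥ 0 branch.  Numerically the
spike-detected oscillatory window is I ∈ (≈0.0345, ≈0.2046): below it the
stable left-branch rest state captures the dynamics, and in the last
≈0.003 before the Hopf point the limit cycle collapses through a canard
stage where the detected pulse duty rises steeply (this band is where the
fastest calibrated frequencies live).  At the reference I₁ = 0.19 the
isolated unit is already (weakly) self-oscillatory; the loop's closed-form
behaviour is therefore entrainment and mutual locking rather than hard
excitation from silence.

## Numerics

- Default integrator: Dormand–Prince RK45 (`scipy.integrate.solve_ivp`)
  with rel_tol 1e−8, abs_tol 1e−10, max step 0.05, sampled on a uniform
  output grid (default spacing 0.01).  The tight tolerances keep limit-cycle
  periods stable well below the 0.1% level used by the locking metrics.
- A fixed-step classic RK4 (`method="fixed_rk4"`, step = `max_step`) serves
  as an independent cross-check; adaptive and fixed solutions agree to
  better than 1e−4 in sup-norm over a 100-unit horizon at the reference
  parameters.
- All runs are deterministic: identical configurations give bit-identical
  trajectories.
- Default horizons: 500 time units for asymptotic metrics (≈27 periods at
  the reference parameters) with the first 30% discarded as transient.
  These sizes keep every analysis comfortably settled while remaining
  desk-scale.

## Measurement operators

**Spike detection** uses hysteresis: a spike opens on an upward crossing of
the up threshold (+1.0 by default — FHN spikes peak near +2) and closes on
the next downward crossing of the down threshold (0.0 by default).
Crossings are located by linear interpolation between samples.  The pulse
*duration* is the time above the down threshold within the spike.  A spike
still open at the end of a record is discarded.  For single excitable
excursions (which return to a rest near u ≈ 0.97 without re-crossing 0) the
thresholds should be raised, e.g. up = 1.5 / down = 1.0; the defaults
target sustained oscillation.

**Time calibration.** The model is dimensionless; physical time enters
only through the anchor "the circuit's mean pulse duration is 25 ms":
`ms_per_unit = 25 / mean_duration`.  Whether the hardware's "25 ms" refers
to a single pulse width or a train envelope is ambiguous in the source
material; the anchor is therefore a parameter (`anchor_ms`), and all
physical frequencies scale inversely with it.  Under this calibration the
pulse repetition frequency is `40·D/P` Hz for duty `D/P`, so 33 Hz
corresponds to a duty of 0.825 — reached only in the canard band near the
upper regime boundary.

**Synchronization** is quantified from spike times, not an analytic-signal
transform: relaxation pulses are strongly non-sinusoidal and spike-phase is
robust and fully specified.  Each channel-2 spike gets a phase by linear
interpolation between the two surrounding channel-1 spikes; the PLV is the
modulus of the mean unit phasor of those phases (1 = perfect locking,
≈n^(−1/2) for independent trains), and the lag is the circular mean phase
times the channel-1 mean period.

**Regime classification** integrates from the rightmost equilibrium
perturbed by +0.1 on `u` and labels the unit oscillatory iff at least 5
spikes fall in the final half of a 500-unit horizon.  The perturbation is
small enough to stay subthreshold in clearly excitable regimes yet seeds
the oscillation when no stable rest state exists; the 5-spike rule is
robust against a single excitable transient spike.  The boundary in `I` is
then located by label bisection.  Where the equilibrium is unique and its
leading eigenvalue is bounded away from zero, the simulation label matches
linear stability; in the bistable low-`I` region only the simulation-based
label is meaningful.

**Coupling sweep.** The experiment's control knob is the stimulus amplitude
reaching the tissue; the model analogue is the forward attenuation `d`.
The sweep reports, per `d`, the asymptotic channel-1 frequency.  By default
the frequency is the *duration-calibrated* physical rate (anchor 25 ms),
which is how a frequency in Hz is read off the hardware: under that
calibration the frequency rises monotonically with `d` (the pulse widens
faster than the period), whereas the raw dimensionless repetition rate
drifts down by ≈2% across d ∈ [0.05, 0.2].  Both readings are available
(`calibration_anchor_ms=None` gives the dimensionless rate).

## Surrogate LFP generator

The generator emulates the *statistics* of stimulus-locked hippocampal LFP
recordings, not any particular dataset: per stimulus, with configurable
probability, an evoked deflection with amplitude drawn uniformly from
10–20 mV is placed one response-delay after the stimulus; a 1 ms
stimulation artifact (biphasic by default) marks the stimulus itself; white
Gaussian noise is added last.  All randomness flows from one integer seed.
Ground truth (which stimuli responded, onset, amplitude, rise slope) is
recorded for recovery tests.

The default evoked template rises **linearly** to its peak (30% of the
pulse width) and decays exponentially (time constant 35% of the width).
The linear rise is deliberate: the two measured indicators — onset-to-peak
amplitude and the slope of the linear rising phase — presume a linear rise,
and this template gives both an exact generating truth
(slope = amplitude / rise time).  A smooth biexponential template is
available (`template="biexponential"`) when waveform realism matters more;
its slope truth is defined as the 20–80% rise secant.  Noise level,
artifact size and response delay defaults are plausible placeholders, not
measured values.

What the surrogate does *not* model: population heterogeneity, synaptic
fatigue and paired-pulse effects, 1/f background activity, electrode drift,
or volume conduction.  Tests passing on surrogate data therefore validate
the measurement operators and pipeline plumbing, not physiological
inference on real recordings.

**Evoked metrics.**  Onset is the departure sample before the signal first
leaves the baseline band (pre-stimulus mean ± 3 SD) for at least 0.5 ms —
the sustained-run rule keeps isolated noise samples from declaring a
response, and a 2 ms post-stimulus blanking interval excludes the artifact
(the standard mitigation, surfaced as a parameter).  Amplitude is the
extremum value minus the onset value.  The linear region is the longest run
of 5-sample windows between onset and peak whose local line fit explains
≥ 98% of local variance; a run covering less than a third of the rise is
treated as spurious and the slope falls back to a fit over the whole rise
(on noisy data the local-R² rule otherwise latches onto short by-chance
stretches).  Truth recovery is exact on noiseless recordings whose stimulus
times and delay are multiples of the sample period (the defaults are).
Polarity is the sign of the dominant deflection, declared indeterminate
when the positive and negative deflections differ by less than 10%.

## Design choices that were genuinely open

- **Default initial condition** of the closed loop: both units at their own
  uncoupled equilibria, matching the experiment's "both at rest, then close
  the loop" protocol.  The open-loop runner instead starts unit 2 at its
  *driven* equilibrium (the constant d·u₁ shift included) so that switching
  the forward path on does not itself fire a spurious spike.
- **Open-loop stimulus**: a rectangular additive pulse on du₁/dt, with no
  claim of fidelity to the hardware pulse shape.  Positive pulses trigger
  excursions (the rest point sits just below the right fold of the cubic).
- **Transient discard** 30% of the horizon everywhere, for consistency of
  asymptotic metrics.
- **Sweep grid over the oscillatory window**: geometric in distance from
  the upper boundary, because the calibrated frequency varies by ≈50%
  within the last ≈2% of the window (canard band) and uniform grids miss
  it.

## Known limitations

- The regime classifier is detection-limited: within ≈0.003 below the Hopf
  point the limit cycle no longer crosses the default thresholds and the
  unit is labelled excitable although a small cycle exists.  The reported
  window is the *spiking* window, which is what the pulse metrics need.
- Physical-unit statements (Hz) inherit the ambiguity of the 25 ms anchor.
- Only two units; no memristive or network extensions, and no stochastic
  variant of the unit dynamics.
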