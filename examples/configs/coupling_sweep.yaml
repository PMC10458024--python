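# Frequency vs forward attenuation d (stimulus-amplitude analogue).
scenario: coupling_sweep
coupling: {k: 0.0223, d: 0.087}
sweep: {d_min: 0.05, d_max: 0.2, n_points: 11, calibration_anchor_ms: 25.0}
solver: {horizon: 500.0, sample_dt: 0.01}
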