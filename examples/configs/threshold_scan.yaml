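# Bisect the excitable/oscillatory boundary of unit 1 in I.
scenario: threshold_scan
unit1: {epsilon: 0.18, I: 0.19}
scan: {i_lo: 0.12, i_hi: 0.35, tol: 1.0e-3, unit: 1}
solver: {horizon: 500.0, sample_dt: 0.01}
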