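# Closed-loop autogenerator at the circuit parameter set.
scenario: closed_loop
unit1: {epsilon: 0.18, I: 0.19, alpha: 0.5, beta: 2.0}
unit2: {epsilon: 0.19, I: 0.18, alpha: 0.5, beta: 2.0}
coupling: {k: 0.0223, d: 0.087, forward_on: true, feedback_on: true}
solver: {horizon: 500.0, sample_dt: 0.01}
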