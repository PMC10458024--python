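# Open loop (no feedback): one rectangular pulse, delayed channel-2 response.
scenario: open_loop
unit1: {epsilon: 0.18, I: 0.23}
unit2: {epsilon: 0.19, I: 0.24}
coupling: {k: 0.0223, d: 0.3, feedback_on: false}
stim: {onsets: [20.0], width: 1.0, amplitude: 1.5}
detection: {up_threshold: 1.5, down_threshold: 1.0}
solver: {horizon: 150.0, sample_dt: 0.01}
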