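# Surrogate LFP: generate, filter, measure evoked responses.
scenario: surrogate_demo
seed: 42
surrogate:
  duration_ms: 1200.0
  noise_sd_mv: 0.5
  response_probability: 0.8
  lowpass_cutoff_hz: 500.0
  window_ms: 40.0
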