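# Full-protocol synthetic run (7 experts / 6 novices, 5 trials of 300 s at
# 25 Hz, both simulators). Reduce sizes for a quick smoke run.
design:
  n_experts: 7
  n_novices: 6
  n_trials: 5
  trial_duration_s: 300.0
  sampling_rate_hz: 25.0
  include_raw: false
windowing:
  window_s: 54.0
gc_band_hz: [0.01, 0.07]
fdr_q: 0.05
removal_p: 0.1
seed: 1
output_dir: nirsnet_output
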