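G_max: 15.0
b_values:
- 250.0
- 500.0
- 750.0
- 1000.0
min_gap_ms: 8.0
n_dir: 6
name: mri-linac-1.5T
readout_margin_ms: 6.0
resolution_delta_ms: 42.0
te_max_ms: 135.0
wf_timings:
- - 42.0
  - 50.0
- - 54.0
  - 62.0
- - 42.0
  - 75.0
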