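G_max: 45.0
b_values:
- 1250.0
- 2500.0
min_gap_ms: 8.0
n_dir: 6
name: conventional-1.5T
readout_margin_ms: 6.0
resolution_delta_ms: 27.0
te_max_ms: 135.0
wf_timings:
- - 27.0
  - 35.0
- - 54.0
  - 62.0
- - 27.0
  - 89.0
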