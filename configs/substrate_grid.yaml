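d0: 2.0
ks_per_s:
- 0.0
- 1.0
- 2.0
- 8.0
- 20.0
radii_um:
- 2.0
- 4.0
- 6.0
- 8.0
- 10.0
- 12.0
- 14.0
- 16.0
- 18.0
- 20.0
vins:
- 0.11
- 0.3
- 0.52
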