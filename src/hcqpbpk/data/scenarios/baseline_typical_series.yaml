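name: baseline_typical_series
kind: simulate
population:
  category: healthy
  age_range:
  - 20
  - 50
  variability: false
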