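name: renal_GFR_lt_30_20_50
kind: population
population:
  category: renal_GFR_lt_30
  age_range:
  - 20
  - 50
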