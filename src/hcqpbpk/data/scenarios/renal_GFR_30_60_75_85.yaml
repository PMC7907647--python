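name: renal_GFR_30_60_75_85
kind: population
population:
  category: renal_GFR_30_60
  age_range:
  - 75
  - 85
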