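name: pediatric_0p5_2y
kind: population
population:
  category: pediatric
  age_range:
  - 0.5
  - 2
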