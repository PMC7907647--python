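name: pediatric_2_6y
kind: population
population:
  category: pediatric
  age_range:
  - 2
  - 6
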