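name: pediatric_1_6mo
kind: population
population:
  category: pediatric
  age_range:
  - 0.083
  - 0.5
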