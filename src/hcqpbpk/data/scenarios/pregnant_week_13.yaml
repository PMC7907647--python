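name: pregnant_week_13
kind: population
population:
  category: pregnant
  age_range:
  - 20
  - 50
  sex_ratio: 0.0
  gestational_week: 13
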