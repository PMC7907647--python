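name: geriatric_85_95
kind: population
population:
  category: geriatric
  age_range:
  - 85
  - 95
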