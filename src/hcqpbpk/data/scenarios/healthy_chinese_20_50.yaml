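name: healthy_chinese_20_50
kind: population
population:
  category: healthy
  age_range:
  - 20
  - 50
  ethnicity: chinese
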