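name: ddi_gemfibrozil_20_50
kind: ddi
perpetrator: gemfibrozil
population:
  category: healthy
  age_range:
  - 20
  - 50
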