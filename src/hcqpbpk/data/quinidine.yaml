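# Quinidine, strong competitive CYP2D6 perpetrator: 200 mg QD for 12 days.
name: quinidine
molecular_weight: 324.42
dose_mg: 200.0
interval_h: 24.0
duration_days: 12.0
ka: 1.5
v_over_f: 190.0
cl_over_f: 20.0
fu_plasma: 0.13
kdeg: 0.0193
inhibition:
  CYP2D6:
    ki_u: 0.06
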