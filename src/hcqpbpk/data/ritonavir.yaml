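# Ritonavir, strong mechanism-based CYP3A4 + weak competitive CYP2D6
# perpetrator: 100 mg QD for 12 days.
name: ritonavir
molecular_weight: 720.94
dose_mg: 100.0
interval_h: 24.0
duration_days: 12.0
ka: 1.0
v_over_f: 96.0
cl_over_f: 8.0
fu_plasma: 0.015
kdeg: 0.0193
inhibition:
  CYP3A4:
    ki_mbi_u: 0.17
    kinact: 20.0
  CYP2D6:
    ki_u: 2.5
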