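# Gemfibrozil, strong CYP2C8 perpetrator: 600 mg BID for 12 days.
# Competitive Ki plus a folded acyl-glucuronide mechanism-based term
# (the metabolite is not modeled explicitly, so its inactivation is
# absorbed into the parent's effective constants).
name: gemfibrozil
molecular_weight: 250.34
dose_mg: 600.0
interval_h: 12.0
duration_days: 12.0
ka: 2.0
v_over_f: 15.0
cl_over_f: 6.0
fu_plasma: 0.03
kdeg: 0.0193                       # 1/h, ~36 h hepatic CYP turnover half-life
inhibition:
  CYP2C8:
    ki_u: 9.3
    ki_mbi_u: 20.0
    kinact: 0.28
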