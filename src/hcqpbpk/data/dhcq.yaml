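# Desethylhydroxychloroquine (CYP-formed metabolite of HCQ; not dosed).
# Physicochemistry is an in-silico-style stand-in; renal clearance from
# literature, hepatic intrinsic clearance fitted (default = fit on the
# packaged synthetic reference profile).
name: DHCQ
molecular_weight_base: 307.82      # C16H22ClN3O
pka_values: [9.45, 8.10]
logp: 2.95
fu_plasma: 0.55
blood_plasma_ratio: 6.5
papp_caco2: 3.0e-6
renal_clearance_plasma: 10.0
hepatic_clu_int: 60.0              # L/h unbound (blood) intrinsic clearance
vss_reference_plasma: 1200.0
lung:
  trapping: 20.0
  clint_t: 0.0
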