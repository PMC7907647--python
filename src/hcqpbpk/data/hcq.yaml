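# Hydroxychloroquine (dosed as the sulfate salt; simulated in base equivalents).
# Binding, B/P, reference clearance and Vss are literature stand-ins; the
# pathway fractions are the disposition contract and hold exactly by
# construction. Units: MW g/mol, permeability cm/s, clearance L/h, Vss L.
name: HCQ
molecular_weight_base: 335.87      # C18H26ClN3O
molecular_weight_salt: 433.95      # C18H26ClN3O . H2SO4
pka_values: [9.67, 8.27]           # diprotic base
logp: 3.58
fu_plasma: 0.5
blood_plasma_ratio: 7.2
papp_caco2: 3.68e-6
fm_map:
  CYP2C8: 0.373
  CYP2D6: 0.193
  CYP3A4: 0.167
  renal: 0.267
reference_plasma_clearance: 42.0
vss_reference_plasma: 1500.0       # effective 10-day-window Vss, not terminal
lung:
  trapping: 20.0
  clint_t: 6.6343                  # L/h; day-6 trough lung:plasma Kp = 200 (analysis/01)
metabolite_links:
  - {enzyme: CYP2C8, formation_fraction: 1.0, product: DHCQ}
  - {enzyme: CYP2D6, formation_fraction: 1.0, product: DHCQ}
  - {enzyme: CYP3A4, formation_fraction: 1.0, product: DHCQ}
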