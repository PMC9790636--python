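enzyme_id: HXK
monitored_species: NADPH
wavelength: 340
direction: increase
monitor_stoichiometry: 1
initial_concentrations:
  NADP: 1.0
  GLC: 10.0
  ATP: 1.0
reactions:
- id: hxk
  role: test
  stoichiometry:
    GLC: -1
    ATP: -1
    G6P: 1
    ADP: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 0.6
    km:
      GLC: 0.08
      ATP: 0.08
      G6P: 30.0
      ADP: 1.0
    keq: HXK
    vmax_units: per_mg_protein
- id: g6pdh
  role: coupling
  stoichiometry:
    G6P: -1
    NADP: -1
    PGL: 1
    NADPH: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 1.8
    km:
      G6P: 0.07
      NADP: 0.02
      PGL: 10.0
      NADPH: 0.1
    keq: 6000.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
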