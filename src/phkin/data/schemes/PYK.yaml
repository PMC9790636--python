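enzyme_id: PYK
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 1
initial_concentrations:
  ADP: 10.0
  NADH: 0.15
  PEP: 2.0
reactions:
- id: pyk
  role: test
  stoichiometry:
    PEP: -1
    ADP: -1
    PYR: 1
    ATP: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 0.6
    km:
      PEP: 0.14
      ADP: 0.53
      PYR: 21.0
      ATP: 1.5
    keq: PYK
    vmax_units: per_mg_protein
- id: ldh
  role: coupling
  stoichiometry:
    PYR: -1
    NADH: -1
    LAC: 1
    NAD: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 13.8
    km:
      PYR: 1.0
      NADH: 0.08
      LAC: 10.0
      NAD: 0.9
    keq: 36000.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
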