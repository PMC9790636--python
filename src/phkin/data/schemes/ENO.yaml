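enzyme_id: ENO
monitored_species: PEP
wavelength: 240
direction: increase
monitor_stoichiometry: 1
initial_concentrations:
  P2G: 6.0
reactions:
- id: eno
  role: test
  stoichiometry:
    P2G: -1
    PEP: 1
  rate_law:
    form: uni_uni_reversible
    vmax: 2.0
    km:
      P2G: 0.04
      PEP: 0.5
    keq: ENO
    vmax_units: per_mg_protein
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
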