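enzyme_id: GAPDHR
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 1
initial_concentrations:
  BPG: 5.0
  NADH: 0.15
reactions:
- id: gapdhr
  role: test
  stoichiometry:
    BPG: -1
    NADH: -1
    GAP: 1
    NAD: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 0.6
    km:
      BPG: 0.01
      NADH: 0.015
      GAP: 1.0
      NAD: 0.5
    keq: 1000.0
    vmax_units: per_mg_protein
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
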