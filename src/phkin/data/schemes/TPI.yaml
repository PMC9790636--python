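enzyme_id: TPI
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 1
initial_concentrations:
  NADH: 0.15
  GAP: 58.0
reactions:
- id: tpi
  role: test
  stoichiometry:
    GAP: -1
    DHAP: 1
  rate_law:
    form: uni_uni_reversible
    vmax: 0.6
    km:
      GAP: 1.27
      DHAP: 6.45
    keq: TPI
    vmax_units: per_mg_protein
- id: g3pdh
  role: coupling
  stoichiometry:
    DHAP: -1
    NADH: -1
    G3P: 1
    NAD: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 8.5
    km:
      DHAP: 0.4
      NADH: 0.05
      G3P: 1.0
      NAD: 0.93
    keq: 10000.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
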