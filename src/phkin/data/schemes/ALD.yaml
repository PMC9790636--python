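enzyme_id: ALD
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 2
initial_concentrations:
  NADH: 0.15
  F16BP: 2.0
reactions:
- id: ald
  role: test
  stoichiometry:
    F16BP: -1
    DHAP: 1
    GAP: 1
  rate_law:
    form: uni_bi_reversible
    vmax: 0.3
    km:
      F16BP: 0.1
      DHAP: 2.4
      GAP: 2.0
    keq: ALD
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
    vmax: 0.6
    km:
      DHAP: 0.4
      NADH: 0.05
      G3P: 1.0
      NAD: 0.93
    keq: 10000.0
    vmax_units: mM_per_min
- id: tpi_c
  role: coupling
  stoichiometry:
    GAP: -1
    DHAP: 1
  rate_law:
    form: uni_uni_reversible
    vmax: 1.8
    km:
      GAP: 1.27
      DHAP: 6.45
    keq: 22.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
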