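enzyme_id: GAPDHF
monitored_species: NADH
wavelength: 340
direction: increase
monitor_stoichiometry: 1
initial_concentrations:
  ADP: 10.0
  NAD: 1.0
  GAP: 5.8
reactions:
- id: gapdhf
  role: test
  stoichiometry:
    GAP: -1
    NAD: -1
    BPG: 1
    NADH: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 0.6
    km:
      GAP: 0.21
      NAD: 0.09
      BPG: 0.05
      NADH: 0.5
    keq: GAPDH
    vmax_units: per_mg_protein
- id: pgk
  role: coupling
  stoichiometry:
    BPG: -1
    ADP: -1
    P3G: 1
    ATP: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 22.5
    km:
      BPG: 0.05
      ADP: 0.2
      P3G: 0.53
      ATP: 0.3
    keq: 3200.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
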