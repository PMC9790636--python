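enzyme_id: PDC
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 1
initial_concentrations:
  NADH: 0.15
  PYR: 50.0
reactions:
- id: pdc
  role: test
  stoichiometry:
    PYR: -1
    AA: 1
    CO2: 1
  non_saturating:
  - CO2
  rate_law:
    form: uni_uni_reversible
    vmax: 0.6
    km:
      PYR: 3.0
      AA: 5.0
    keq: PDC
    vmax_units: per_mg_protein
- id: adh
  role: coupling
  stoichiometry:
    AA: -1
    NADH: -1
    EtOH: 1
    NAD: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 88.0
    km:
      AA: 1.1
      NADH: 0.11
      EtOH: 17.0
      NAD: 0.17
    keq: 14000.0
    vmax_units: mM_per_min
ph: 6.8
protein: 0.1
dilution_factor: 1
coupling_surplus: 1000.0
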