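enzyme_id: PGM
monitored_species: NADH
wavelength: 340
direction: decrease
monitor_stoichiometry: 1
initial_concentrations:
  ADP: 10.0
  NADH: 0.15
  P3G: 5.0
reactions:
- id: pgm
  role: test
  stoichiometry:
    P3G: -1
    P2G: 1
  rate_law:
    form: uni_uni_reversible
    vmax: 0.6
    km:
      P3G: 0.5
      P2G: 0.08
    keq: PGM
    vmax_units: per_mg_protein
- id: eno_c
  role: coupling
  stoichiometry:
    P2G: -1
    PEP: 1
  rate_law:
    form: uni_uni_reversible
    vmax: 2.0
    km:
      P2G: 0.04
      PEP: 0.5
    keq: 6.7
    vmax_units: mM_per_min
- id: pyk_c
  role: coupling
  stoichiometry:
    PEP: -1
    ADP: -1
    PYR: 1
    ATP: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 13.0
    km:
      PEP: 0.14
      ADP: 0.53
      PYR: 21.0
      ATP: 1.5
    keq: 6500.0
    vmax_units: mM_per_min
- id: ldh
  role: coupling
  stoichiometry:
    PYR: -1
    NADH: -1
    LAC: 1
    NAD: 1
  rate_law:
    form: bi_bi_reversible
    vmax: 11.3
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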