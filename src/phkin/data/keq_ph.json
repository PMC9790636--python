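{
  "description": "Synthetic frozen Keq(pH) tables for the assay test reactions. Generated from log10 Keq(pH) = log10 Keq(6.8) + n*(pH-6.8); not retrieved from a thermodynamics service.",
  "reference_ph": 6.8,
  "parameters": {
    "HXK": {
      "keq_at_6p8": 2000.0,
      "dlog10keq_dph": 1.0
    },
    "PGI": {
      "keq_at_6p8": 0.29,
      "dlog10keq_dph": 0.05
    },
    "PFK": {
      "keq_at_6p8": 800.0,
      "dlog10keq_dph": 0.75
    },
    "ALD": {
      "keq_at_6p8": 0.069,
      "dlog10keq_dph": 0.1
    },
    "TPI": {
      "keq_at_6p8": 22.0,
      "dlog10keq_dph": 0.02
    },
    "GAPDH": {
      "keq_at_6p8": 0.01,
      "dlog10keq_dph": 1.25
    },
    "PGM": {
      "keq_at_6p8": 0.19,
      "dlog10keq_dph": 0.03
    },
    "ENO": {
      "keq_at_6p8": 6.7,
      "dlog10keq_dph": 0.08
    },
    "PYK": {
      "keq_at_6p8": 6500.0,
      "dlog10keq_dph": 0.6
    },
    "PDC": {
      "keq_at_6p8": 10000.0,
      "dlog10keq_dph": 0.9
    }
  }
}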