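{
  "PVD": {
    "hr": 0.79,
    "relative_weight": 1.0,
    "integer_weight": 1
  },
  "UD": {
    "hr": 0.8,
    "relative_weight": 1.013,
    "integer_weight": 1
  },
  "MLD": {
    "hr": 0.88,
    "relative_weight": 1.114,
    "integer_weight": 1
  },
  "CTD": {
    "hr": 0.89,
    "relative_weight": 1.127,
    "integer_weight": 1
  },
  "DM": {
    "hr": 0.94,
    "relative_weight": 1.19,
    "integer_weight": 1
  },
  "CPD": {
    "hr": 0.95,
    "relative_weight": 1.203,
    "integer_weight": 1
  },
  "MI": {
    "hr": 1.26,
    "relative_weight": 1.595,
    "integer_weight": 2
  },
  "DMW": {
    "hr": 1.31,
    "relative_weight": 1.658,
    "integer_weight": 2
  },
  "CVD": {
    "hr": 1.35,
    "relative_weight": 1.709,
    "integer_weight": 2
  },
  "CHF": {
    "hr": 1.54,
    "relative_weight": 1.949,
    "integer_weight": 2
  },
  "HEMI": {
    "hr": 1.57,
    "relative_weight": 1.987,
    "integer_weight": 2
  },
  "DEME": {
    "hr": 1.81,
    "relative_weight": 2.291,
    "integer_weight": 2
  },
  "MSRD": {
    "hr": 1.86,
    "relative_weight": 2.354,
    "integer_weight": 2
  },
  "TUM": {
    "hr": 2.88,
    "relative_weight": 3.646,
    "integer_weight": 4
  },
  "MSLD": {
    "hr": 2.94,
    "relative_weight": 3.722,
    "integer_weight": 4
  },
  "AIDS": {
    "hr": 3.64,
    "relative_weight": 4.608,
    "integer_weight": 5
  },
  "MST": {
    "hr": 4.29,
    "relative_weight": 5.43,
    "integer_weight": 5
  }
}
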