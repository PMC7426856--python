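{
  "MI": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "CHF": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "PVD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "CVD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "DEME": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "CPD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "CTD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "UD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "MLD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "DM": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 1
  },
  "HEMI": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 2
  },
  "DMW": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 2
  },
  "MSRD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 2
  },
  "TUM": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 2
  },
  "MSLD": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 3
  },
  "MST": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 6
  },
  "AIDS": {
    "hr": null,
    "relative_weight": null,
    "integer_weight": 6
  }
}
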