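{
  "version": "published-final-v1",
  "feature_units": "pixels",
  "intercept": 34.406,
  "coefficients": {
    "branch_length_max": 0.022,
    "branch_width_max": -0.092,
    "branch_width_min": 0.155,
    "branch_thickness_max": -0.122,
    "branch_thickness_min": -1.667,
    "density": -0.124
  },
  "mapping": {
    "branch_length_max": "branch_length_max",
    "branch_width_max": "branch_width_max",
    "branch_width_min": "branch_width_min",
    "branch_thickness_max": "branch_thickness_max",
    "branch_thickness_min": "branch_thickness_min",
    "density": "density"
  }
}
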