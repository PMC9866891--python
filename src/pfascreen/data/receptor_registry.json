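{
  "version": 1,
  "units": "kcal/mol",
  "note": "Published standardized-space MLR equations and binding-class thresholds for five nuclear hormone receptors.",
  "receptors": {
    "PPARA": {
      "pdb": "3KDU",
      "descriptors": ["ICR", "PW2"],
      "intercept": -7.499,
      "intercept_se": 0.067,
      "coefficients": [-0.947, -0.394],
      "coefficient_ses": [0.070, 0.070],
      "thresholds": [-10.0, -9.4, -8.9]
    },
    "PPARB": {
      "pdb": "3GZ9",
      "descriptors": ["ICR", "X%"],
      "intercept": -8.248,
      "intercept_se": 0.069,
      "coefficients": [-1.059, -0.409],
      "coefficient_ses": [0.071, 0.071],
      "thresholds": [-10.5, -10.1, -9.6]
    },
    "PPARG": {
      "pdb": "3ET3",
      "descriptors": ["ICR", "X%"],
      "intercept": -7.727,
      "intercept_se": 0.052,
      "coefficients": [-1.099, -0.398],
      "coefficient_ses": [0.053, 0.053],
      "thresholds": [-10.3, -9.6, -8.9]
    },
    "TRA": {
      "pdb": "3ILZ",
      "descriptors": ["X%", "ICR"],
      "intercept": -8.230,
      "intercept_se": 0.070,
      "coefficients": [-0.454, -1.189],
      "coefficient_ses": [0.071, 0.071],
      "thresholds": [-10.2, -9.2, -7.2]
    },
    "TRB": {
      "pdb": "3IMY",
      "descriptors": ["X%", "TPC"],
      "intercept": -8.724,
      "intercept_se": 0.054,
      "coefficients": [-0.137, -1.509],
      "coefficient_ses": [0.061, 0.061],
      "thresholds": [-10.5, -9.4, -7.8]
    }
  }
}
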