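name: terazosin
title: Terazosin HCl dihydrate matrix tablets, 5 screened factors, 11 time points
notes:
  - >-
    The source study screened ten formulation factors down to five (PEO,
    Syloid, NaH2PO4, citric acid, Polyox N10) by stepwise regression; only
    the five screened factors and their surfaces are stored.  Factor symbols
    keep their original indices (x1, x3, x7, x8, x10).
  - >-
    The reported natural-unit optimum for NaH2PO4 (103.675) differs from the
    decode of its reported coded value (14.748 * 7.03 = 103.678) in the last
    printed digit.
  - >-
    The stored surfaces are incompatible with the stored profile limits: the
    fitted 1 h mean never reaches its LSL of 8.8 anywhere in the coded box
    (its maximum is about 8.36), and at the reported optimum ten of the
    eleven fitted means fall outside their limits.  Maximizing the composite
    desirability for this fixture therefore reports total infeasibility with
    a per-component diagnostic; the fixture is retained for coding and
    transcription regression only.
factors:
  - symbol: x1
    name: PEO
    unit: mg
    levels: [93.71, 100.77, 107.77, 171.04, 234.31]
    center: 93.71
    scale: 7.03
  - symbol: x3
    name: Syloid
    unit: mg
    levels: [0, 7.03, 14.06, 77.33, 140.6]
    center: 0
    scale: 7.03
  - symbol: x7
    name: NaH2PO4
    unit: mg
    levels: [0, 7.03, 14.06, 77.33, 140.6]
    center: 0
    scale: 7.03
  - symbol: x8
    name: Citric acid
    unit: mg
    levels: [0, 7.03, 14.06, 77.33, 140.6]
    center: 0
    scale: 7.03
  - symbol: x10
    name: Polyox N10
    unit: mg
    levels: [0, 7.03, 14.06, 77.33, 140.6]
    center: 0
    scale: 7.03
responses:
  - {label: y1, time: 0.5, kind: NTB, lsl: 4.8, target: 6, usl: 7.2}
  - {label: y2, time: 1.0, kind: NTB, lsl: 8.8, target: 11, usl: 13.2}
  - {label: y3, time: 1.5, kind: NTB, lsl: 10.24, target: 12.8, usl: 15.36}
  - {label: y4, time: 2.0, kind: NTB, lsl: 12.88, target: 16.1, usl: 19.32}
  - {label: y5, time: 3.0, kind: NTB, lsl: 18.08, target: 22.6, usl: 27.12}
  - {label: y6, time: 4.0, kind: NTB, lsl: 23.84, target: 29.8, usl: 35.76}
  - {label: y7, time: 6.0, kind: NTB, lsl: 34.8, target: 43.5, usl: 52.2}
  - {label: y8, time: 8.0, kind: NTB, lsl: 41.12, target: 51.4, usl: 61.68}
  - {label: y9, time: 10.0, kind: NTB, lsl: 48.24, target: 60.3, usl: 72.36}
  - {label: y10, time: 12.0, kind: NTB, lsl: 54.8, target: 68.5, usl: 82.2}
  - {label: y11, time: 24.0, kind: NTB, lsl: 65.84, target: 82.3, usl: 98.76}
term_order: &tz ["1", x1, x3, x7, x8, x10, x1^2, x3^2, x7^2, x8^2, x10^2, x1*x3]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *tz,
     coefficients: [4.844, -0.039, 0.023, -0.006, -0.005, -0.001, 0.0001, -0.00007, 0.00006, 0.00002, 0.00003, 0.0006]}
  - {label: var_y1, role: variance, response: y1, terms: *tz,
     coefficients: [0.71, -0.008, 0.0001, -0.00078, 0.006, -0.006, 0.00003, 0.000006, 0.00003, -0.00002, 0.00004, -0.00003]}
  - {label: mu_y2, role: mean, response: y2, terms: *tz,
     coefficients: [7.644, -0.027, 0.015, -0.01, 0.017, -0.014, 0.0001, 0.000001, 0.0001, 0.0002, 0.0001, 0.0004]}
  - {label: var_y2, role: variance, response: y2, terms: *tz,
     coefficients: [1.103, -0.041, -0.027, -0.002, 0.021, 0.006, 0.0001, 0.00008, 0.00002, -0.00007, -0.00002, 0.0009]}
  - {label: mu_y3, role: mean, response: y3, terms: *tz,
     coefficients: [7.228, 0.109, 0.018, -0.029, 0.033, -0.035, -0.0003, -0.0005, 0.0003, 0.0003, 0.0002, -0.0044]}
  - {label: var_y3, role: variance, response: y3, terms: *tz,
     coefficients: [0.292, 0.021, 0.035, -0.031, 0.033, -0.004, -0.00005, -0.000009, 0.0002, -0.0001, 0.00003, -0.0009]}
  - {label: mu_y4, role: mean, response: y4, terms: *tz,
     coefficients: [8.611, 0.165, 0.248, -0.074, 0.074, -0.05, -0.0005, -0.0007, 0.0006, 0.0002, 0.0003, -0.006]}
  - {label: var_y4, role: variance, response: y4, terms: *tz,
     coefficients: [1.582, -0.082, -0.05, -0.033, 0.058, 0.027, 0.0003, 0.0002, 0.0002, -0.0002, -0.0001, 0.002]}
  - {label: mu_y5, role: mean, response: y5, terms: *tz,
     coefficients: [12.428, 0.207, 0.309, -0.09, 0.089, -0.049, -0.0006, -0.0008, 0.0007, 0.0003, 0.0004, -0.008]}
  - {label: var_y5, role: variance, response: y5, terms: *tz,
     coefficients: [1.69, -0.078, -0.033, -0.021, 0.052, 0.033, 0.0003, 0.0001, 0.0001, -0.0002, -0.0001, 0.001]}
  - {label: mu_y6, role: mean, response: y6, terms: *tz,
     coefficients: [16.417, 0.287, 0.388, -0.11, 0.126, -0.07, -0.0008, -0.001, 0.0009, 0.0003, 0.0005, -0.011]}
  - {label: var_y6, role: variance, response: y6, terms: *tz,
     coefficients: [3.123, -0.134, -0.074, -0.035, 0.061, 0.053, 0.0005, 0.0002, 0.0002, -0.0002, -0.0002, 0.003]}
  - {label: mu_y7, role: mean, response: y7, terms: *tz,
     coefficients: [21.874, 0.563, 0.691, -0.174, 0.109, -0.084, -0.002, -0.002, 0.001, 0.0006, 0.0007, -0.02]}
  - {label: var_y7, role: variance, response: y7, terms: *tz,
     coefficients: [4.719, -0.22, -0.104, -0.056, 0.073, 0.105, 0.0008, 0.0003, 0.0003, -0.0002, -0.0004, 0.005]}
  - {label: mu_y8, role: mean, response: y8, terms: *tz,
     coefficients: [28.588, 0.811, 0.963, -0.221, 0.073, -0.11, -0.002, -0.003, 0.001, 0.0007, 0.001, -0.03]}
  - {label: var_y8, role: variance, response: y8, terms: *tz,
     coefficients: [5.417, -0.226, -0.064, -0.072, 0.061, 0.158, 0.0008, 0.0001, 0.0004, -0.0002, -0.0006, 0.004]}
  - {label: mu_y9, role: mean, response: y9, terms: *tz,
     coefficients: [37.1, 0.886, 1.086, -0.249, 0.058, -0.094, -0.003, -0.003, 0.002, 0.001, 0.001, -0.032]}
  - {label: var_y9, role: variance, response: y9, terms: *tz,
     coefficients: [7.351, -0.28, -0.085, -0.088, 0.046, 0.201, 0.001, 0.0002, 0.0005, -0.0002, -0.0008, 0.005]}
  - {label: mu_y10, role: mean, response: y10, terms: *tz,
     coefficients: [44.362, 1.017, 1.237, -0.229, 0.055, -0.144, -0.003, -0.004, 0.001, 0.0006, 0.001, -0.036]}
  - {label: var_y10, role: variance, response: y10, terms: *tz,
     coefficients: [7.482, -0.267, -0.049, -0.095, 0.055, 0.217, 0.001, 0.00001, 0.0005, -0.0002, -0.001, 0.004]}
  - {label: mu_y11, role: mean, response: y11, terms: *tz,
     coefficients: [82.688, 0.577, 0.705, -0.056, 0.06, 0.044, -0.002, -0.002, 0.004, -0.00004, 0.0001, -0.02]}
  - {label: var_y11, role: variance, response: y11, terms: *tz,
     coefficients: [7.503, -0.104, -0.025, -0.097, -0.005, -0.004, 0.0005, 0.00004, 0.0006, -0.0001, -0.0001, 0.001]}
reported_optimum:
  coded: [15.556, 0.691, 14.748, 0.0, 20.0]
  natural: [203.069, 4.858, 103.675, 0.0, 140.6]
  coding_consistent: [true, true, false, true, true]
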