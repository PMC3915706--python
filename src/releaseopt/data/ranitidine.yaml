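name: ranitidine
title: Ranitidine floating matrix, 2 factors, 3 time points plus f2 index
notes:
  - >-
    The reported natural-unit optimum for the gelucire amount (657.7288 mg)
    contradicts its reported coded value under the stored coding
    (-0.909 * 168 + 672 = 519.288 mg).  The reported values are stored as
    printed and flagged.
  - >-
    The f2 similarity index was fitted as a response surface in its own
    right; it is a scalar response (no time point).  Its desirability is LTB
    with lower acceptable value 50 (the conventional similarity threshold)
    and upper ideal 100 (identical profiles).
factors:
  - symbol: x1
    name: Amount of gelucire 43/01
    unit: mg
    levels: [504, 672, 840]
    center: 672
    scale: 168
  - symbol: x2
    name: Amount of ethylcellulose
    unit: mg
    levels: [84, 168, 252]
    center: 168
    scale: 84
responses:
  - {label: y1, time: 1.0, kind: NTB, lsl: 26, target: 32.5, usl: 39}
  - {label: y2, time: 5.0, kind: NTB, lsl: 54, target: 67.5, usl: 81}
  - {label: y3, time: 10.0, kind: NTB, lsl: 68, target: 85, usl: 102}
  - {label: f2, kind: LTB, lsl: 50, target: 100,
     weights: {mean: 1, var: 0, cv: 0, cov: 0}}
term_order: &full2 ["1", x1, x2, x1^2, x2^2, x1*x2]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *full2,
     coefficients: [37.191, -7.918, -3.955, 1.148, -1.432, -0.558]}
  - {label: var_y1, role: variance, response: y1, terms: *full2,
     coefficients: [1.957, 0.862, -0.693, -0.105, -0.04, -1.32]}
  - {label: cv_y1, role: cv, response: y1, terms: *full2,
     coefficients: [0.038, 0.015, -0.003, -0.002, -0.001, -0.012]}
  - {label: mu_y2, role: mean, response: y2, terms: *full2,
     coefficients: [75.29, -6.358, -8.795, 1.035, -1.345, 0.745]}
  - {label: var_y2, role: variance, response: y2, terms: *full2,
     coefficients: [5.129, 0.25, 0.915, -2.223, -0.583, -1.18]}
  - {label: cv_y2, role: cv, response: y2, terms: *full2,
     coefficients: [0.031, 0.003, 0.006, -0.009, -0.002, -0.005]}
  - {label: mu_y3, role: mean, response: y3, terms: *full2,
     coefficients: [89.216, -8.49, -7.528, 3.797, -1.728, -3.195]}
  - {label: var_y3, role: variance, response: y3, terms: *full2,
     coefficients: [3.026, -0.145, -1.292, 2.372, -1.968, 0.75]}
  - {label: cv_y3, role: cv, response: y3, terms: *full2,
     coefficients: [0.017, 0.002, -0.003, 0.007, -0.004, -0.003]}
  - {label: f2, role: scalar, response: f2, terms: *full2,
     coefficients: [50.157, 7.52, 9.473, -5.26, -1.49, -0.66]}
reported_optimum:
  coded: [-0.909, 1.0]
  natural: [657.7288, 252.0]
  coding_consistent: [false, true]
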