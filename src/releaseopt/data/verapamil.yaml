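name: verapamil
title: Verapamil HCl coated pellets, 3 factors, 5 time points
notes:
  - >-
    The reported natural-unit optimum for coating duration (29.8176 h)
    contradicts its reported coded value under the stored coding
    (0.5152 * 12 + 36 = 42.1824 h); 29.8176 equals 36 - 0.5152 * 12, i.e. a
    sign flip.  The reported values are stored as printed and flagged.
factors:
  - symbol: x1
    name: Coating weight gain
    unit: "%"
    levels: [8, 11, 14]
    center: 11
    scale: 3
  - symbol: x2
    name: Duration of coating
    unit: h
    levels: [24, 36, 48]
    center: 36
    scale: 12
  - symbol: x3
    name: Amount of plasticizer
    unit: "%"
    levels: [60, 90, 120]
    center: 90
    scale: 30
responses:
  - {label: y1, time: 2.0, kind: NTB, lsl: 13.36, target: 16.7, usl: 20.04}
  - {label: y2, time: 4.0, kind: NTB, lsl: 26.64, target: 33.3, usl: 39.96}
  - {label: y3, time: 6.0, kind: NTB, lsl: 40, target: 50, usl: 60}
  - {label: y4, time: 9.0, kind: NTB, lsl: 50, target: 75, usl: 90}
  - {label: y5, time: 12.0, kind: NTB, lsl: 80, target: 100, usl: 120}
term_order: &full3 ["1", x1, x2, x3, x1^2, x2^2, x3^2, x1*x2, x1*x3, x2*x3]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *full3,
     coefficients: [12.986, -2.16, -1.0, 0.68, 0.121, -0.279, 0.221, 0.038, 0.038, 0.163]}
  - {label: var_y1, role: variance, response: y1, terms: *full3,
     coefficients: [1.274, 0.057, 0.33, -0.235, -0.064, 0.056, -0.298, -0.002, 0.426, 0.292]}
  - {label: cv_y1, role: cv, response: y1, terms: *full3,
     coefficients: [0.082, 0.013, 0.017, -0.015, -0.006, 0.011, -0.016, 0.002, 0.014, 0.015]}
  - {label: mu_y2, role: mean, response: y2, terms: *full3,
     coefficients: [25.121, -5.2, -2.0, 1.43, 0.47, -0.331, 0.619, 0.163, 0.063, 0.338]}
  - {label: var_y2, role: variance, response: y2, terms: *full3,
     coefficients: [1.747, 0.112, 0.004, -0.564, -1.017, 1.813, -0.732, -0.442, 0.185, -0.185]}
  - {label: cv_y2, role: cv, response: y2, terms: *full3,
     coefficients: [0.046, 0.01, 0.002, -0.011, -0.013, 0.025, -0.009, -0.004, 0.0004, -0.004]}
  - {label: mu_y3, role: mean, response: y3, terms: *full3,
     coefficients: [42.938, -7.27, -2.87, 2.31, -0.257, -0.257, -0.057, 0.913, 0.463, -0.688]}
  - {label: var_y3, role: variance, response: y3, terms: *full3,
     coefficients: [3.412, 0.072, 0.965, 0.052, 3.869, -1.106, -1.351, -1.126, 0.936, -0.049]}
  - {label: cv_y3, role: cv, response: y3, terms: *full3,
     coefficients: [0.042, 0.009, 0.008, -0.002, -0.023, -0.005, -0.007, -0.006, 0.004, 0.001]}
  - {label: mu_y4, role: mean, response: y4, terms: *full3,
     coefficients: [67.278, -11.37, -3.02, 3.27, -2.541, 3.709, -3.841, 0.125, 0.825, 0.05]}
  - {label: var_y4, role: variance, response: y4, terms: *full3,
     coefficients: [3.563, 0.311, -0.064, 0.085, -0.895, 0.32, 0.425, 0.523, -0.208, -0.09]}
  - {label: cv_y4, role: cv, response: y4, terms: *full3,
     coefficients: [0.027, 0.007, 0.002, -0.002, -0.001, 0.001, 0.003, 0.003, -0.002, -0.001]}
  - {label: mu_y5, role: mean, response: y5, terms: *full3,
     coefficients: [82.395, -12.84, -5.25, 3.8, -0.567, -0.417, 0.333, -0.675, 0.625, 0.125]}
  - {label: var_y5, role: variance, response: y5, terms: *full3,
     coefficients: [3.944, -0.428, 0.038, -0.142, 1.018, -1.592, -0.662, 0.705, -0.065, 0.643]}
  - {label: cv_y5, role: cv, response: y5, terms: *full3,
     coefficients: [0.024, 0.002, 0.002, -0.002, 0.004, -0.006, -0.002, 0.003, -0.001, 0.003]}
reported_optimum:
  coded: [-0.6566, 0.5152, 1.0]
  natural: [9.0302, 29.8176, 120.0]
  coding_consistent: [true, false, true]
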