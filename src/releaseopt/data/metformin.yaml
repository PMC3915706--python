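name: metformin
title: Metformin gel beads, 3 factors, 3 time points
notes:
  - >-
    The source prints the sodium-alginate coding as "(x1 - 1.758)/1.25",
    which is inconsistent with the levels (1.25/1.75/2.25 %) and with the
    reported decode (coded 1 -> 2.25 %).  The stored coding uses center 1.75,
    scale 0.5, which reproduces the reported optimum table.
  - >-
    The reported optimum is not the maximizer of the equal-weight composite
    desirability assembled from these surfaces: at (1, -0.9192, -1) the
    fitted 0.5 h mean is 25.98 against a USL of 26 (d = 0.009) and every
    dispersion surface exceeds its value at the composite maximizer.  It is
    retained for reference only.
factors:
  - symbol: x1
    name: Concentration of sodium alginate
    unit: "%"
    levels: [1.25, 1.75, 2.25]
    center: 1.75
    scale: 0.5
  - symbol: x2
    name: Concentration of gellan gum
    unit: "%"
    levels: [0, 0.25, 0.5]
    center: 0.25
    scale: 0.25
  - symbol: x3
    name: Concentration of metformin
    unit: "%"
    levels: [2.5, 3.75, 5]
    center: 3.75
    scale: 1.25
responses:
  - {label: y1, time: 0.5, kind: NTB, lsl: 21, target: 23.5, usl: 26}
  - {label: y2, time: 3.5, kind: NTB, lsl: 62, target: 63.5, usl: 65}
  - {label: y3, time: 8.0, kind: NTB, lsl: 91, target: 92.5, usl: 94}
term_order: &full3 ["1", x1, x2, x3, x1^2, x2^2, x3^2, x1*x2, x1*x3, x2*x3]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *full3,
     coefficients: [31.153, -3.546, -3.884, 3.243, 0.667, 1.874, -3.391, 2.897, -0.767, 1.175]}
  - {label: var_y1, role: variance, response: y1, terms: *full3,
     coefficients: [0.669, -0.456, -0.45, -0.839, 1.542, -1.429, 2.026, -1.309, -1.167, 0.649]}
  - {label: cv_y1, role: cv, response: y1, terms: *full3,
     coefficients: [0.028, 0.002, 0.0004, -0.016, 0.01, -0.01, 0.022, -0.016, -0.01, 0.002]}
  - {label: mu_y2, role: mean, response: y2, terms: *full3,
     coefficients: [64.474, -6.603, -4.648, 3.1, -0.977, 4.658, 1.287, -1.168, -0.65, -0.705]}
  - {label: var_y2, role: variance, response: y2, terms: *full3,
     coefficients: [0.841, -0.063, 0.215, 0.12, -0.173, 0.765, 0.048, -0.084, -0.56, -0.371]}
  - {label: cv_y2, role: cv, response: y2, terms: *full3,
     coefficients: [0.011, 0.001, 0.003, -0.001, -0.001, 0.007, -0.0003, -0.00003, -0.004, -0.002]}
  - {label: mu_y3, role: mean, response: y3, terms: *full3,
     coefficients: [92.466, -4.383, -2.878, 1.811, -1.242, 2.206, -0.987, -1.1, 0.168, 2.018]}
  - {label: var_y3, role: variance, response: y3, terms: *full3,
     coefficients: [0.895, -0.192, 0.213, -0.302, 0.029, -0.564, 0.786, -0.135, 0.088, -0.284]}
  - {label: cv_y3, role: cv, response: y3, terms: *full3,
     coefficients: [0.01, -0.001, 0.001, -0.001, 0.0001, -0.004, 0.004, -0.001, 0.001, -0.001]}
reported_optimum:
  coded: [1.0, -0.9192, -1.0]
  natural: [2.25, 0.0202, 2.5]
  coding_consistent: [true, true, true]
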