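name: diclofenac
title: Diclofenac sodium microspheres, 3 factors, 3 profile time points
notes:
  - >-
    The covariance surface cov_y1_y3 contains a typographically garbled term
    in its source ("1.603x11.572x2"); it is stored here as +1.603*x1 and
    -1.572*x2.  The sign of the x2 coefficient is unrecoverable from the
    source; any result leaning on this surface should be read with that in
    mind.
  - >-
    The reported optimum is not the maximizer of the equal-weight composite
    desirability assembled from these surfaces: at (-0.7576, -0.3939, 1) the
    fitted 6 h mean is 69.57 against a 60 target (d = 0.043) and the 8 h mean
    79.84 against 72.5 (d = 0.021).  It is retained for reference only.
factors:
  - symbol: x1
    name: Stirring speed
    unit: rpm
    levels: [500, 1000, 1500]
    center: 1000
    scale: 500
  - symbol: x2
    name: Concentration of calcium chloride
    unit: "%"
    levels: [5, 10, 15]
    center: 10
    scale: 5
  - symbol: x3
    name: Percentage of liquid paraffin
    unit: "%"
    levels: [0, 25, 50]
    center: 25
    scale: 25
responses:
  - {label: y1, time: 1.0, kind: NTB, lsl: 20, target: 30, usl: 40}
  - {label: y2, time: 6.0, kind: NTB, lsl: 50, target: 60, usl: 70}
  - {label: y3, time: 8.0, kind: NTB, lsl: 65, target: 72.5, usl: 80}
term_order: &full3 ["1", x1, x2, x3, x1^2, x2^2, x3^2, x1*x2, x1*x3, x2*x3]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *full3,
     coefficients: [39.929, 2.365, -2.206, -1.959, 0.202, 1.971, -0.912, -1.389, 0.797, 0.079]}
  - {label: mu_y2, role: mean, response: y2, terms: *full3,
     coefficients: [73.368, 4.388, -5.031, -2.379, 0.399, 0.579, -0.127, -1.525, -0.062, -0.359]}
  - {label: mu_y3, role: mean, response: y3, terms: *full3,
     coefficients: [83.203, 4.165, -4.562, -2.498, -0.624, -0.907, 1.176, -2.37, 0.151, -1.632]}
  - {label: var_y1, role: variance, response: y1, terms: *full3,
     coefficients: [7.31, -0.642, 0.032, 2.799, 1.698, 5.377, 4.895, 5.543, 1.893, -0.686]}
  - {label: var_y2, role: variance, response: y2, terms: *full3,
     coefficients: [5.74, -1.195, 1.609, -5.458, 7.112, 0.037, 9.608, 11.9, -4.042, 0.98]}
  - {label: var_y3, role: variance, response: y3, terms: *full3,
     coefficients: [11.548, -6.216, 3.632, -0.354, 2.053, 2.293, 2.581, -5.282, 2.575, -5.902]}
  - {label: cv_y1, role: cv, response: y1, terms: *full3,
     coefficients: [0.063, -0.005, -0.001, 0.012, 0.007, 0.008, 0.014, 0.021, 0.008, -0.003]}
  - {label: cv_y2, role: cv, response: y2, terms: *full3,
     coefficients: [0.04, -0.002, 0.007, -0.003, 0.006, -0.004, 0.009, 0.013, -0.008, 0.004]}
  - {label: cv_y3, role: cv, response: y3, terms: *full3,
     coefficients: [0.039, -0.009, 0.008, 0.002, -0.0002, 0.004, 0.006, -0.007, 0.002, -0.006]}
  - {label: cov_y1_y2, role: covariance, pair: [y1, y2], terms: *full3,
     coefficients: [1.89, 2.507, -0.799, 0.299, 0.677, -2.227, -4.571, -2.594, -0.655, -2.289]}
  - {label: cov_y1_y3, role: covariance, pair: [y1, y3], terms: *full3,
     coefficients: [1.091, 1.603, -1.572, 3.023, -3.872, -3.299, 3.353, -1.879, 0.966, 2.559]}
  - {label: cov_y2_y3, role: covariance, pair: [y2, y3], terms: *full3,
     coefficients: [-2.945, -1.711, -1.729, -3.296, 2.541, 2.411, -2.738, -0.22, 3.237, 3.732]}
reported_optimum:
  coded: [-0.7576, -0.3939, 1.0]
  natural: [621.2, 8.0305, 50.0]
  coding_consistent: [true, true, true]
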