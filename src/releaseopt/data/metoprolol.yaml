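name: metoprolol
title: Metoprolol hydrophilic matrix, 2 factors, 3 time points plus t50/MDT/f2
notes:
  - >-
    Only mean-type surfaces exist for this study (no variance/CV/covariance
    fits were published); the composite uses the three profile means, t50,
    MDT and f2 only.
  - >-
    t50 (time to 50 % release) and MDT (mean dissolution time) carry printed
    NTB limits; f2 has none and is assigned the LTB convention (lower
    acceptable 50, upper ideal 100).
  - >-
    The t50 surface omits the x1*x2 interaction in the source; the term set
    is stored exactly as printed.
factors:
  - symbol: x1
    name: Percentage of xanthan gum
    unit: "%"
    levels: [20, 30, 40]
    center: 30
    scale: 10
  - symbol: x2
    name: Percentage of Methocel
    unit: "%"
    levels: [10, 20, 30]
    center: 20
    scale: 10
responses:
  - {label: y1, time: 1.0, kind: NTB, lsl: 15, target: 17.5, usl: 20}
  - {label: y2, time: 4.0, kind: NTB, lsl: 20, target: 30, usl: 40}
  - {label: y3, time: 12.0, kind: NTB, lsl: 60, target: 65, usl: 70}
  - {label: t50, kind: NTB, lsl: 6, target: 7, usl: 8,
     weights: {mean: 1, var: 0, cv: 0, cov: 0}}
  - {label: MDT, kind: NTB, lsl: 8, target: 9, usl: 10,
     weights: {mean: 1, var: 0, cv: 0, cov: 0}}
  - {label: f2, kind: LTB, lsl: 50, target: 100,
     weights: {mean: 1, var: 0, cv: 0, cov: 0}}
term_order: &full2 ["1", x1, x2, x1^2, x2^2, x1*x2]
surfaces:
  - {label: mu_y1, role: mean, response: y1, terms: *full2,
     coefficients: [20.778, -3.317, -4.017, 0.183, -0.917, -0.325]}
  - {label: mu_y2, role: mean, response: y2, terms: *full2,
     coefficients: [38.678, -4.5, -5.7, 1.583, -1.467, -1.425]}
  - {label: mu_y3, role: mean, response: y3, terms: *full2,
     coefficients: [68.822, -5.483, -5.5, 2.317, -1.333, 0.15]}
  - {label: t50, role: scalar, response: t50,
     terms: ["1", x1, x2, x1^2, x2^2],
     coefficients: [6.222, 1.0, 1.167, -0.333, 0.167]}
  - {label: MDT, role: scalar, response: MDT, terms: *full2,
     coefficients: [8.222, 0.767, 0.933, -0.333, 0.267, -0.1]}
  - {label: f2, role: scalar, response: f2, terms: *full2,
     coefficients: [68.556, 11.183, 11.45, -2.483, -3.583, -1.525]}
reported_optimum:
  coded: [0.0458, 0.6726]
  natural: [30.458, 26.726]
  coding_consistent: [true, true]
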