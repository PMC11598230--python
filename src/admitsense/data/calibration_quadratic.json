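{
  "description": "Published quadratic response-surface calibration of the prototype coplanar-electrode admittance sensor. alpha = [a0, a1, a2, a3, a4] in V(x1,x2) = a0 + a1*x1 + a2*x1^2 + a3*x2 + a4*x2^2, with x1 = NaCl mM, x2 = KCl mM, response in deionized-water-referenced volts. r is the reported Pearson fit diagnostic on the authors' dataset.",
  "models": [
    {"frequency_hz": 5000.0, "channel": "quadrature", "alpha": [-0.169, 0.438, 0.016, 0.519, 0.025], "r": 0.998},
    {"frequency_hz": 5000.0, "channel": "in_phase", "alpha": [0.684, 1.604, -0.120, 1.816, -0.117], "r": 0.985},
    {"frequency_hz": 10000.0, "channel": "quadrature", "alpha": [-0.08, 0.236, 0.020, 0.309, 0.023], "r": 0.998},
    {"frequency_hz": 10000.0, "channel": "in_phase", "alpha": [0.367, 1.275, -0.083, 1.503, -0.089], "r": 0.995}
  ]
}
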