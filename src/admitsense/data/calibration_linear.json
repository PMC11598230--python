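{
  "description": "Published linear response-surface calibration of the same device (a2 = a4 = 0). The quadrature rows are the ones used for closed-form initialization of the two-frequency estimator.",
  "models": [
    {"frequency_hz": 5000.0, "channel": "quadrature", "alpha": [-0.246, 0.502, 0, 0.62, 0], "r": 0.997},
    {"frequency_hz": 5000.0, "channel": "in_phase", "alpha": [1.143, 1.110, 0, 1.333, 0], "r": 0.979},
    {"frequency_hz": 10000.0, "channel": "quadrature", "alpha": [-0.163, 0.318, 0, 0.405, 0], "r": 0.996},
    {"frequency_hz": 10000.0, "channel": "in_phase", "alpha": [0.7, 0.932, 0, 1.137, 0], "r": 0.990}
  ]
}
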