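{
  "coefficients": [0.752, 0.686, 0.774, 0.244, 0.491, 0.387],
  "norm_min": [21.97, 12.1, 23.4, 0.0, 130.0, 0.5],
  "norm_range": [26.23, 25.47, 39.3, 4.2, 360.0, 0.85],
  "scale_factor": 10.0,
  "skin_temp_threshold": 35.0,
  "bands": [
    {"label": "Low", "lower": null},
    {"label": "Moderate", "lower": 12.02},
    {"label": "High", "lower": 15.88},
    {"label": "Very high", "lower": 17.56}
  ]
}
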