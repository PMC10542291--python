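{
  "name": "synthetic-linear-v1",
  "mean_coeffs": [50.0, 8.0],
  "sd_coeffs": [3.5, 0.56],
  "ga_range": [14.0, 42.0]
}
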