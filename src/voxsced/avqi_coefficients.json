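{
  "default": "v3-adapted",
  "sets": {
    "v3-adapted": {
      "intercept": 3.295,
      "cpps": -0.111,
      "hnr": -0.073,
      "shimmer_pct": -0.213,
      "shimmer_db": 2.789,
      "ltas_slope": -0.032,
      "ltas_tilt": 0.077,
      "scale": 2.571,
      "cutoff": 2.33
    },
    "equal-weight-demo": {
      "intercept": 5.0,
      "cpps": -0.2,
      "hnr": -0.1,
      "shimmer_pct": 0.1,
      "shimmer_db": 1.0,
      "ltas_slope": 0.0,
      "ltas_tilt": 0.0,
      "scale": 1.0,
      "cutoff": 2.33
    }
  }
}
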