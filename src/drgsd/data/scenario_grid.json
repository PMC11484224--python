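{
  "description": "Default comparison grid: every combination of spending family, interim information fraction and pipeline information fraction, for all three designs.",
  "alpha": 0.025,
  "beta": 0.2,
  "sigma": 1.0,
  "n_max_per_arm": 200,
  "info_interim": [0.3, 0.4, 0.5],
  "info_pipeline": [0.1, 0.2, 0.3],
  "spending_family": ["pocock_like", "obrien_fleming_like"],
  "delta_range": [-0.4, 0.8],
  "delta_points": 13
}
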