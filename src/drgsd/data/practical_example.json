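{
  "description": "Two-arm phase III trial with a delayed continuous endpoint (negative-symptom score): interim after 200 of 690 observed outcomes with 208 patients in the pipeline.",
  "design": {
    "alpha": 0.025,
    "beta": 0.2,
    "sigma": 7.5,
    "n_max_per_arm": 345,
    "info_interim": 0.29,
    "info_pipeline": 0.3,
    "spending_family": "pocock_like",
    "design_kind": "GSD"
  },
  "delta": 1.6
}
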