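{
  "description": "Reference boundary sets and operating characteristics for the packaged worked example (Pocock-like spending, I1=0.29, I_dt=0.3, delta=1.6, sigma=7.5, n_max=345/arm), rounded to 3 decimals; used as a regression anchor for the example command.",
  "fixed_design": {"d2": 1.96, "power": 0.8, "n_total": 690},
  "GSD": {
    "l1": 0.259, "u1": 2.322, "d1": null, "d2": 2.119,
    "p_futility": 0.106, "p_reject_interim": 0.208,
    "power": 0.722, "expected_n_total": 601.286
  },
  "DR_GSD": {
    "l1": 0.259, "u1": 2.322, "d1": 1.584, "d2": 2.119,
    "p_futility": 0.089, "p_reject_interim": 0.224,
    "power": 0.739, "expected_n_total": 601.286
  },
  "RR_GSD": {
    "l1": -0.164, "u1": 1.815, "d1": 1.96, "d2": 2.043,
    "p_futility": 0.098, "p_reject_interim": 0.329,
    "power": 0.737, "expected_n_total": 569.222
  }
}
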