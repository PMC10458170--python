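{
  "alpha": 0.21,
  "beta": 1.76,
  "gamma": -0.46,
  "epsilon": 72.59,
  "scope": "high_score_only",
  "threshold_lhsd": 1.47
}
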