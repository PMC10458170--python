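{
  "alpha": 3.10,
  "beta": 2.03,
  "gamma": 2.29,
  "epsilon": 54.27,
  "scope": "all",
  "threshold_lhsd": 1.47
}
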