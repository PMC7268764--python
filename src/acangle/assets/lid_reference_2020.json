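{
  "name": "lid-reference-2020",
  "version": 1,
  "alpha1": -2.111,
  "alpha2": 0.019,
  "beta": {"lid": 10.231}
}
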