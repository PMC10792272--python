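{
  "descriptor": "planted low-rank regression n=12 p=3 r=2 q=1",
  "noise_sd": 0.0,
  "rank": 2,
  "seed": 0,
  "weights": [
    [
      0.4294842949858664
    ],
    [
      -0.4224463579937263
    ],
    [
      -0.9652126568871129
    ]
  ]
}
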