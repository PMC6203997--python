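{
  "n": 141,
  "names": ["satisfaction_man", "anxiety_man", "satisfaction_woman", "anxiety_woman"],
  "means": [39.31, 6.52, 39.26, 8.09],
  "sds": [6.56, 4.30, 6.70, 4.46],
  "correlations": [
    [1.0, -0.336, 0.423, -0.235],
    [-0.336, 1.0, -0.159, 0.209],
    [0.423, -0.159, 1.0, -0.316],
    [-0.235, 0.209, -0.316, 1.0]
  ]
}
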