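{
  "shells": [
    {"label": "Small", "lower": 92.8, "upper": 101.8},
    {"label": "Medium", "lower": 100.3, "upper": 109.4},
    {"label": "Large", "lower": 107.8, "upper": 116.9}
  ],
  "profiles": {
    "Small": [
      {"label": "I", "lower": 8.5, "upper": 9.5},
      {"label": "II", "lower": 9.3, "upper": 10.3},
      {"label": "III", "lower": 10.1, "upper": 11.1}
    ],
    "Medium": [
      {"label": "I", "lower": 8.8, "upper": 9.8},
      {"label": "II", "lower": 9.6, "upper": 10.6},
      {"label": "III", "lower": 10.5, "upper": 11.5}
    ],
    "Large": [
      {"label": "I", "lower": 9.3, "upper": 10.2},
      {"label": "II", "lower": 10.0, "upper": 11.0},
      {"label": "III", "lower": 10.8, "upper": 11.7}
    ]
  },
  "mean_A": {
    "Small/I": 21.6,
    "Small/II": 22.8,
    "Small/III": 23.2,
    "Medium/I": 22.6,
    "Medium/II": 24.4,
    "Medium/III": 24.2,
    "Large/I": 21.7,
    "Large/II": 24.2,
    "Large/III": 23.8
  },
  "mean_sigma": {
    "Small/I": 9.1,
    "Small/II": 9.9,
    "Small/III": 10.4,
    "Medium/I": 9.3,
    "Medium/II": 10.2,
    "Medium/III": 10.7,
    "Large/I": 9.7,
    "Large/II": 10.5,
    "Large/III": 11.2
  },
  "n_cohort": 200
}
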