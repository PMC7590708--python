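{
  "comment": "Published FRéLE cut-point dialect (reference fixture for dialect tests).",
  "thresholds": {
    "exhaustion": {"all": 46.88},
    "activity": {"female": 32.33, "male": 39.35},
    "slowness": {
      "female|short": 5.6,
      "female|tall": 6.54,
      "male|short": 6.3,
      "male|tall": 7.0
    },
    "weakness": {
      "female|q1": 37.0,
      "female|q2": 35.0,
      "female|q3": 35.0,
      "female|q4": 35.0,
      "female|q5": 35.0,
      "male|q1": 47.4,
      "male|q2": 55.0,
      "male|q3": 55.0,
      "male|q4": 53.6,
      "male|q5": 55.0
    }
  },
  "height_split_cm": {"female": 155.81, "male": 169.55},
  "bmi_edges": {
    "female": [23.49, 25.97, 28.56, 32.11],
    "male": [24.17, 26.42, 28.59, 31.31]
  }
}
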