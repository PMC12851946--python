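{
  "immune_activity": {
    "genes": ["GZMB", "IFNG", "CD8A", "PRF1", "CXCL13"]
  },
  "rankl_signaling": {
    "genes": ["TNFSF11", "TNFRSF11B", "TNF"],
    "weights": [1.0, -1.0, 1.0]
  },
  "steroid_sensitivity": {
    "genes": ["NR3C1", "TSC22D3", "FKBP5"]
  },
  "chemo_response": {
    "genes": ["MKI67", "TOP2A", "TYMS"],
    "weights": [-1.0, -1.0, -1.0]
  }
}
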