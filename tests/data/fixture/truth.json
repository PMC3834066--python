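{
  "context_assignment": {
    "P0002|D001": [
      "C00002",
      "C00001"
    ],
    "P0002|P0003": [
      "C00001",
      "C00002"
    ],
    "P0002|P0004": [
      "C00002",
      "C00001"
    ]
  },
  "gd_pairs": [
    [
      "P0002",
      "D001"
    ]
  ],
  "ppi_pairs": [
    [
      "P0002",
      "P0004"
    ],
    [
      "P0002",
      "P0003"
    ]
  ]
}
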