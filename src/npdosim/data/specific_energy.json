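{
  "AGuIX": {
    "cell": "SQ20B", "beam": "250kVp",
    "z_bar_Gy": {"whole_cell": 8.2e-4, "cytoplasm": 6.4e-4, "nuclear_membrane": 9.1e-4}
  },
  "AuNP50": {
    "cell": "Hela", "beam": "220kVp",
    "z_bar_Gy": {"whole_cell": 2.0e-3, "cytoplasm": 1.7e-3, "nuclear_membrane": 2.6e-3}
  }
}
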