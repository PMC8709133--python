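{
  "SQ20B": {"r_cell": 10.6, "r_nucleus": 8.1, "rho": 1.0},
  "Hela": {"r_cell": 8.6, "r_nucleus": 5.5, "rho": 1.0},
  "A549": {"r_cell": 7.4, "r_nucleus": 4.8, "rho": 1.0}
}
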