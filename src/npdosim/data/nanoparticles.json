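{
  "AGuIX": {"diameter_nm": 3.0, "density_gcc": 1.2},
  "AuNP50": {"diameter_nm": 50.0, "density_gcc": 19.32}
}
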