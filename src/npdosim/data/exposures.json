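{
  "AGuIX": {
    "250kVp": {
      "lam": 0.168, "lam_sigma": 0.003,
      "mu": 3.00e-7, "mu_sigma": 0.06e-7,
      "p1Gy": 5.04e-8, "p1Gy_sigma": 0.14e-8
    }
  },
  "AuNP50": {
    "105kVp": {
      "lam": 46.1, "lam_sigma": 0.9,
      "mu": 6.41e-4, "mu_sigma": 0.13e-4,
      "p1Gy": 2.96e-2, "p1Gy_sigma": 0.08e-2
    },
    "220kVp": {
      "lam": 47.7, "lam_sigma": 1.0,
      "mu": 4.09e-4, "mu_sigma": 0.08e-4,
      "p1Gy": 1.95e-2, "p1Gy_sigma": 0.05e-2
    },
    "Cs137": {
      "lam": 5.97, "lam_sigma": 0.12,
      "mu": 8.96e-6, "mu_sigma": 0.18e-6,
      "p1Gy": 5.35e-5, "p1Gy_sigma": 0.15e-5
    },
    "6MV": {
      "lam": 2.63, "lam_sigma": 0.05,
      "mu": 4.63e-6, "mu_sigma": 0.09e-6,
      "p1Gy": 1.22e-5, "p1Gy_sigma": 0.03e-5
    }
  }
}
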