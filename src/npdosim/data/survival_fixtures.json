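{
  "SQ20B_AGuIX_250kVp": {
    "cell": "SQ20B", "np": "AGuIX", "beam": "250kVp", "n_np": 6.06e8,
    "alpha": 0.04, "alpha_sigma": null, "beta": 0.05,
    "alpha_np": 0.5, "alpha_np_sigma": null, "beta_np": 0.03,
    "source": "Miladi et al., 0.6 mM AGuIX, 250 kVp"
  },
  "A549_AGuIX_250kVp_lo": {
    "cell": "A549", "np": "AGuIX", "beam": "250kVp", "n_np": 1.66e7,
    "alpha": 0.332, "alpha_sigma": 0.045, "beta": 0.018,
    "alpha_np": 0.349, "alpha_np_sigma": 0.054, "beta_np": 0.018,
    "source": "Liu et al. (pHLIP-free AGuIX, low uptake); beta from Wera et al., assumed unchanged"
  },
  "A549_AGuIX_250kVp_hi": {
    "cell": "A549", "np": "AGuIX", "beam": "250kVp", "n_np": 1.32e9,
    "alpha": 0.332, "alpha_sigma": 0.045, "beta": 0.018,
    "alpha_np": 0.488, "alpha_np_sigma": 0.063, "beta_np": 0.018,
    "source": "Liu et al. (pHLIP-conjugated AGuIX, high uptake); beta from Wera et al., assumed unchanged"
  },
  "Hela_AuNP_105kVp": {
    "cell": "Hela", "np": "AuNP50", "beam": "105kVp", "n_np": 6000,
    "alpha": 0.237, "alpha_sigma": 0.005, "beta": 0.041,
    "alpha_np": 0.528, "alpha_np_sigma": 0.007, "beta_np": 0.054,
    "source": "Chithrani et al., 50 nm AuNP, 105 kVp"
  },
  "Hela_AuNP_220kVp": {
    "cell": "Hela", "np": "AuNP50", "beam": "220kVp", "n_np": 6000,
    "alpha": 0.150, "alpha_sigma": 0.004, "beta": 0.041,
    "alpha_np": 0.352, "alpha_np_sigma": 0.005, "beta_np": 0.041,
    "source": "Chithrani et al., 50 nm AuNP, 220 kVp"
  },
  "Hela_AuNP_Cs137": {
    "cell": "Hela", "np": "AuNP50", "beam": "Cs137", "n_np": 6000,
    "alpha": 0.119, "alpha_sigma": 0.013, "beta": 0.040,
    "alpha_np": 0.259, "alpha_np_sigma": 0.011, "beta_np": 0.030,
    "source": "Chithrani et al., 50 nm AuNP, Cs-137 (660 keV)"
  },
  "Hela_AuNP_6MV": {
    "cell": "Hela", "np": "AuNP50", "beam": "6MV", "n_np": 6000,
    "alpha": 0.110, "alpha_sigma": 0.008, "beta": 0.029,
    "alpha_np": 0.191, "alpha_np_sigma": 0.002, "beta_np": 0.031,
    "source": "Chithrani et al., 50 nm AuNP, 6 MV"
  },
  "Cal33_AGuIX_250kVp": {
    "cell": null, "np": "AGuIX", "beam": "250kVp", "n_np": null,
    "alpha": -0.05, "alpha_sigma": null, "beta": 0.08,
    "alpha_np": 0.07, "alpha_np_sigma": null, "beta_np": 0.11,
    "source": "Miladi et al., Cal33 (negative fitted alpha; stored as-is)"
  }
}
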