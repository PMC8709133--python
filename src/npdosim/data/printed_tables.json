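{
  "table2": [
    {"np": "AGuIX", "scenario": "whole_cell", "n_np": 6.06e8,
     "delta_xi": [0.027, 0.078], "dalpha_ratio": 0.034, "der": 1.025, "rbe_2gy": [1.016, 1.020]},
    {"np": "AGuIX", "scenario": "whole_cell", "n_np": 6.06e9,
     "delta_xi": [0.27, 0.78], "dalpha_ratio": 0.34, "der": 1.25, "rbe_2gy": [1.15, 1.19]},
    {"np": "AGuIX", "scenario": "cytoplasm", "n_np": 6.06e8,
     "delta_xi": [0.020, 0.059], "dalpha_ratio": 0.025, "der": 1.019, "rbe_2gy": [1.012, 1.015]},
    {"np": "AGuIX", "scenario": "cytoplasm", "n_np": 6.06e9,
     "delta_xi": [0.20, 0.59], "dalpha_ratio": 0.25, "der": 1.19, "rbe_2gy": [1.12, 1.15]},
    {"np": "AGuIX", "scenario": "nuclear_membrane", "n_np": 6.06e8,
     "delta_xi": [0.031, 0.089], "dalpha_ratio": 0.038, "der": 1.027, "rbe_2gy": [1.017, 1.022]},
    {"np": "AGuIX", "scenario": "nuclear_membrane", "n_np": 6.06e9,
     "delta_xi": [0.31, 0.89], "dalpha_ratio": 0.38, "der": 1.27, "rbe_2gy": [1.16, 1.21]},
    {"np": "AuNP50", "scenario": "whole_cell", "n_np": 6000,
     "delta_xi": 0.93, "dalpha_ratio": 0.25, "der": 1.24, "rbe_2gy": 1.31},
    {"np": "AuNP50", "scenario": "whole_cell", "n_np": 18000,
     "delta_xi": 2.8, "dalpha_ratio": 0.76, "der": 1.71, "rbe_2gy": null},
    {"np": "AuNP50", "scenario": "cytoplasm", "n_np": 6000,
     "delta_xi": 0.75, "dalpha_ratio": 0.21, "der": 1.20, "rbe_2gy": 1.25},
    {"np": "AuNP50", "scenario": "cytoplasm", "n_np": 18000,
     "delta_xi": 2.3, "dalpha_ratio": 0.62, "der": 1.59, "rbe_2gy": null},
    {"np": "AuNP50", "scenario": "nuclear_membrane", "n_np": 6000,
     "delta_xi": 1.20, "dalpha_ratio": 0.33, "der": 1.30, "rbe_2gy": 1.38},
    {"np": "AuNP50", "scenario": "nuclear_membrane", "n_np": 18000,
     "delta_xi": 3.6, "dalpha_ratio": 0.98, "der": 1.91, "rbe_2gy": null}
  ],
  "table2_known_discrepancies": [
    {"np": "AGuIX", "scenario": "nuclear_membrane", "quantity": "der",
     "reason": "printed 1.027/1.27 not reachable from the 2-s.f. mean specific energy 9.1e-4 Gy (computed 1.0278/1.278); unrounded internals presumed"}
  ],
  "table3": {
    "SQ20B_AGuIX_250kVp": {"p1": 0.015, "p1_sigma": null,
      "sf_base": 0.76, "sf_np": 0.33, "rbe_2gy": 2.17},
    "A549_AGuIX_250kVp_lo": {"p1": [0.0, 5.6e-2], "p1_sigma": null,
      "sf_base": 0.48, "sf_np": 0.46, "rbe_2gy": 1.04},
    "A549_AGuIX_250kVp_hi": {"p1": 2.34e-3, "p1_sigma": 0.67e-3,
      "sf_base": 0.48, "sf_np": 0.35, "rbe_2gy": 1.37},
    "Hela_AuNP_105kVp": {"p1": 1.64e-3, "p1_sigma": 0.04e-3,
      "sf_base": 0.53, "sf_np": 0.28, "rbe_2gy": 1.69},
    "Hela_AuNP_220kVp": {"p1": 1.73e-3, "p1_sigma": 0.05e-3,
      "sf_base": 0.63, "sf_np": 0.42, "rbe_2gy": 1.56},
    "Hela_AuNP_Cs137": {"p1": 0.436, "p1_sigma": 0.055,
      "sf_base": 0.67, "sf_np": 0.53, "rbe_2gy": 1.39},
    "Hela_AuNP_6MV": {"p1": 1.11, "p1_sigma": 0.12,
      "sf_base": 0.71, "sf_np": 0.60, "rbe_2gy": 1.35}
  },
  "distance_model_a_um": {
    "SQ20B": [0.147, 0.234],
    "Hela": 0.122
  },
  "xi_sensitivity_Gy": {
    "SQ20B": [0.8, 2.33]
  },
  "bomb_predictions": {
    "fixture": "Hela_AuNP_220kVp",
    "delta_alpha": 0.202,
    "rbe_2gy": 1.56,
    "rbe_2gy_doubled": 2.02
  }
}
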