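{
  "format": "mixqspr-linear-model",
  "version": 1,
  "feature_names": [
    "P_VSA_MR_6_pmix",
    "Eig02_EA(dm)_pmix",
    "CATS2D_02_AN_pmix",
    "BLTF96_pmix",
    "MATS5s_nmix",
    "temperature"
  ],
  "coef": [0.405, -5.034, -23.145, 8.835, -25.191, -0.104],
  "intercept": 89.611,
  "coef_se": [0.026, 0.874, 3.32, 0.174, 2.352, 0.011],
  "intercept_se": 3.452,
  "stats": {
    "r2": 0.916,
    "r2_adj": 0.915,
    "f_stat": 642.4,
    "n_train": 360,
    "rho": 60.0,
    "residual_sd": null
  },
  "warning": null,
  "trace": [],
  "metadata": {
    "name": "M12",
    "response": "surface tension, mN/m",
    "descriptor_method": 2,
    "split": {"scheme": "MO", "seed": 4, "interval": 3},
    "scoring": "R2",
    "reported": {
      "q2_loo": 0.908,
      "mae_loo": 2.608,
      "q2_lco": 0.882,
      "mae_lco": 3.122,
      "r2_pred_test": 0.783,
      "mae_test": 5.134,
      "r2_pred_ext": 0.862,
      "mae_ext": 1.777,
      "aard_train": 5.805,
      "aard_test": 11.155,
      "aard_ext": 4.418,
      "crp2": 0.908
    }
  }
}
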