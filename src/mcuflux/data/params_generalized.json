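{
  "_comment": "Published generalized-GHK (present) formulation estimates. K0 in uM, k0 in nmol/mg/s. Datasets: heart = rat-heart Ca2+ titration, liver = rat-liver Ca2+ titration, liver_dpsi = rat-liver membrane-potential titration (rate constants vary across preparations; K0, alpha, nH are shared per tissue).",
  "model1": {
    "heart":      {"k0_nmol_mg_s": 0.0159, "K0_uM": 87.6, "alpha": 0.0, "nH": 2.65},
    "liver":      {"k0_nmol_mg_s": 0.0142, "K0_uM": 45.6, "alpha": 0.0, "nH": 2.65},
    "liver_dpsi": {"k0_nmol_mg_s": 1.99,   "K0_uM": 45.6, "alpha": 0.0, "nH": 2.65}
  },
  "model2": {
    "heart":      {"k0_nmol_mg_s": 0.01972, "K0_uM": 72.8, "alpha": 0.0, "nH": 2.65},
    "liver":      {"k0_nmol_mg_s": 0.01775, "K0_uM": 37.9, "alpha": 0.0, "nH": 2.65},
    "liver_dpsi": {"k0_nmol_mg_s": 1.42,    "K0_uM": 37.9, "alpha": 0.0, "nH": 2.65}
  }
}
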