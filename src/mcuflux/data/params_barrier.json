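{
  "_comment": "Published Eyring-barrier (previous) formulation estimates, re-fit under alpha_e = alpha_x = alpha >= 0. Binding constants in molar, rate constants in nmol/mg/s. Case 2 entries are the m = 1 member of the degenerate family (K_x0 -> m*K_x0, k_out0 -> m^2*k_out0 all fit equally well).",
  "model1": {
    "case1": {
      "heart":      {"k_in0_nmol_mg_s": 0.34, "K_e0_M": 88.1e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver":      {"k_in0_nmol_mg_s": 0.30, "K_e0_M": 45.9e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver_dpsi": {"k_in0_nmol_mg_s": 44.5, "K_e0_M": 45.9e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887}
    },
    "case2": {
      "heart":      {"k_in0_nmol_mg_s": 0.34, "k_out0_nmol_mg_s": 0.34, "K_e0_M": 88.1e-6, "K_x0_M": 88.1e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver":      {"k_in0_nmol_mg_s": 0.30, "k_out0_nmol_mg_s": 0.30, "K_e0_M": 45.9e-6, "K_x0_M": 45.9e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver_dpsi": {"k_in0_nmol_mg_s": 44.5, "k_out0_nmol_mg_s": 44.5, "K_e0_M": 45.9e-6, "K_x0_M": 45.9e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887}
    }
  },
  "model2": {
    "case1": {
      "heart":      {"k_in0_nmol_mg_s": 0.43, "K_e0_M": 74.3e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver":      {"k_in0_nmol_mg_s": 0.38, "K_e0_M": 38.7e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver_dpsi": {"k_in0_nmol_mg_s": 32.6, "K_e0_M": 38.7e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887}
    },
    "case2": {
      "heart":      {"k_in0_nmol_mg_s": 0.43, "k_out0_nmol_mg_s": 0.43, "K_e0_M": 74.3e-6, "K_x0_M": 74.3e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver":      {"k_in0_nmol_mg_s": 0.38, "k_out0_nmol_mg_s": 0.38, "K_e0_M": 38.7e-6, "K_x0_M": 38.7e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887},
      "liver_dpsi": {"k_in0_nmol_mg_s": 32.6, "k_out0_nmol_mg_s": 32.6, "K_e0_M": 38.7e-6, "K_x0_M": 38.7e-6, "alpha_e": 0.0, "alpha_x": 0.0, "beta_e": 0.113, "beta_x": 0.887}
    }
  }
}
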