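{
  "description": "Measured/derived parameter sets for the CMC polyelectrolyte vs 150 mM NaCl model system. Concentrations in mM, diffusion coefficients in m2_per_s, chemical-potential corrections in units of RT, relaxivities in per_mM_per_s.",
  "constants": {
    "temperature_K": 298.15,
    "epsilon_r": 78,
    "c_nacl_salt_mM": 150.0,
    "c_gd_salt_initial_mM": 0.33,
    "c_gd_salt_experimental_mM": 0.36,
    "d_na_m2_per_s": 1.33e-09,
    "d_cl_m2_per_s": 2.03e-09,
    "d_gd_salt_m2_per_s": 4.5e-10,
    "d_gd_membrane_m2_per_s": 1.5e-10,
    "relaxivity_salt_per_mM_per_s": 3.84
  },
  "sets": {
    "fcd-73": {
      "fcd_mM": -73.0,
      "c_na_poly_mM": 202.0,
      "c_cl_poly_mM": 129.0,
      "relaxivity_poly_per_mM_per_s": 3.92,
      "d_gd_poly_m2_per_s": 4.1e-10,
      "delta_mu_na_RT": -0.0958,
      "delta_mu_cl_RT": -0.0512,
      "delta_mu_gd_RT": -0.205
    },
    "fcd-92": {
      "fcd_mM": -92.0,
      "c_na_poly_mM": 216.0,
      "c_cl_poly_mM": 124.0,
      "relaxivity_poly_per_mM_per_s": 3.94,
      "d_gd_poly_m2_per_s": 3.9e-10,
      "delta_mu_na_RT": -0.1105,
      "delta_mu_cl_RT": -0.0635,
      "delta_mu_gd_RT": -0.26
    },
    "fcd-108": {
      "fcd_mM": -108.0,
      "c_na_poly_mM": 223.0,
      "c_cl_poly_mM": 115.0,
      "relaxivity_poly_per_mM_per_s": 3.96,
      "d_gd_poly_m2_per_s": 3.7e-10,
      "delta_mu_na_RT": -0.1211,
      "delta_mu_cl_RT": -0.0099,
      "delta_mu_gd_RT": -0.25
    },
    "fcd-50-low": {
      "fcd_mM": -50.0,
      "d_gd_poly_m2_per_s": 4.2e-10,
      "delta_mu_na_RT": -0.0736,
      "delta_mu_cl_RT": -0.041,
      "delta_mu_gd_RT": -0.125
    },
    "fcd-150-stress": {
      "fcd_mM": -150.0,
      "d_gd_poly_m2_per_s": 3.5e-10,
      "delta_mu_na_RT": -0.14,
      "delta_mu_cl_RT": -0.095,
      "delta_mu_gd_RT": -0.318
    },
    "ideal": {
      "fcd_mM": 0.0,
      "d_gd_poly_m2_per_s": 4.5e-10,
      "delta_mu_na_RT": 0.0,
      "delta_mu_cl_RT": 0.0,
      "delta_mu_gd_RT": 0.0
    }
  }
}
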