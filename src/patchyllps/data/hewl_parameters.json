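{
  "schema": "patchyllps/parameters-v1",
  "comment": "Hen egg-white lysozyme (HEWL) coarse-grained model and per-buffer interaction parameters at pH 7.0, 0.1 M buffers. Uncertainties and measured kD / B22 / Jones-Dole B values are carried as metadata.",
  "model": {
    "sigma": 3.43,
    "omega": 0.18,
    "n_sites": 10,
    "molar_mass": 14300.0
  },
  "buffers": [
    {
      "name": "phosphate",
      "eps0": 2250.0,
      "salt_coeff": 500.0,
      "jones_dole_b": 0.50,
      "metadata": {
        "eps0_sd": 10.0,
        "salt_coeff_sd": 20.0,
        "jones_dole_b_25C": 0.50,
        "jones_dole_b_25C_sd": 0.02,
        "jones_dole_b_5C": 0.47,
        "jones_dole_b_5C_sd": 0.04,
        "kd_ml_g": -7.1,
        "kd_ml_g_sd": 0.8,
        "b22_mol_ml_g2": -1.2e-4,
        "b22_mol_ml_g2_sd": 0.2e-4
      }
    },
    {
      "name": "HEPES",
      "eps0": 2140.0,
      "salt_coeff": 630.0,
      "jones_dole_b": 0.60,
      "metadata": {
        "eps0_sd": 10.0,
        "salt_coeff_sd": 40.0,
        "jones_dole_b_25C": 0.60,
        "jones_dole_b_25C_sd": 0.06,
        "jones_dole_b_5C": 0.66,
        "jones_dole_b_5C_sd": 0.06,
        "kd_ml_g": 13.5,
        "kd_ml_g_sd": 0.5,
        "b22_mol_ml_g2": 2.0e-4,
        "b22_mol_ml_g2_sd": 2.2e-4
      }
    },
    {
      "name": "MOPS",
      "eps0": 1990.0,
      "salt_coeff": 890.0,
      "jones_dole_b": 0.74,
      "metadata": {
        "eps0_sd": 10.0,
        "salt_coeff_sd": 40.0,
        "jones_dole_b_25C": 0.74,
        "jones_dole_b_25C_sd": 0.13,
        "jones_dole_b_5C": 0.79,
        "jones_dole_b_5C_sd": 0.17,
        "kd_ml_g": 11.0,
        "kd_ml_g_sd": 2.0,
        "b22_mol_ml_g2": 5.9e-4,
        "b22_mol_ml_g2_sd": 0.2e-4
      }
    },
    {
      "name": "cacodylate",
      "eps0": 1940.0,
      "salt_coeff": 1090.0,
      "jones_dole_b": 0.52,
      "metadata": {
        "eps0_sd": 20.0,
        "salt_coeff_sd": 70.0,
        "jones_dole_b_25C": 0.52,
        "jones_dole_b_25C_sd": 0.05,
        "jones_dole_b_5C": 0.84,
        "jones_dole_b_5C_sd": 0.15,
        "kd_ml_g": 12.0,
        "kd_ml_g_sd": 1.0,
        "b22_mol_ml_g2": 3.1e-4,
        "b22_mol_ml_g2_sd": 0.2e-4
      }
    }
  ]
}
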