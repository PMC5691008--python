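{
  "air": {
    "density_g_cm3": 0.0012047,
    "mode": "weight",
    "composition": {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012828}
  },
  "water": {
    "density_g_cm3": 1.0,
    "mode": "molecular",
    "composition": {"H": 2, "O": 1}
  },
  "pmma": {
    "density_g_cm3": 1.18,
    "mode": "molecular",
    "composition": {"C": 5, "O": 2, "H": 8}
  },
  "aluminum": {
    "density_g_cm3": 2.699,
    "mode": "molecular",
    "composition": {"Al": 1}
  },
  "soft_tissue": {
    "density_g_cm3": 1.06,
    "mode": "weight",
    "composition": {"H": 0.102, "C": 0.143, "N": 0.034, "O": 0.718, "P": 0.003},
    "note": "ICRU-44 adult soft tissue; trace Na/S/Cl/K (1.0% by weight) folded into O"
  },
  "lung": {
    "density_g_cm3": 0.26,
    "mode": "weight",
    "composition": {"H": 0.103, "C": 0.105, "N": 0.031, "O": 0.759, "P": 0.002},
    "note": "ICRU-44 lung (inflated); trace Na/S/Cl/K (1.0%) folded into O"
  },
  "cortical_bone": {
    "density_g_cm3": 1.92,
    "mode": "weight",
    "composition": {"H": 0.034, "C": 0.155, "N": 0.042, "O": 0.441, "P": 0.103, "Ca": 0.225},
    "note": "ICRU-44 cortical bone; trace Na/Mg/S (0.6%) folded into O"
  },
  "cancellous_bone": {
    "density_g_cm3": 1.18,
    "mode": "weight",
    "composition": {"H": 0.085, "C": 0.404, "N": 0.058, "O": 0.375, "P": 0.034, "Ca": 0.044},
    "note": "ICRU-44 spongiosa; trace Na/S/Cl/K/Fe (0.7%) folded into O"
  }
}
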