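{
  "water": {
    "density_g_cm3": 1.0,
    "composition_percent": {"H": 11.2, "O": 88.8},
    "notes": "reference medium for PDD and RD"
  },
  "polystyrene": {
    "density_g_cm3": 1.06,
    "composition_percent": {"H": 7.8, "C": 92.2},
    "notes": "bolus material"
  },
  "PLA": {
    "density_g_cm3": 1.1245,
    "composition_percent": {"H": 5.6, "C": 50.0, "O": 44.4},
    "notes": "polylactic acid, 3D-printable bolus material"
  },
  "glycerol": {
    "density_g_cm3": 1.2613,
    "composition_percent": {"H": 8.8, "C": 39.1, "O": 52.1},
    "notes": "bolus material"
  },
  "silica-gel": {
    "density_g_cm3": 1.155,
    "composition_percent": {"H": 8.1, "C": 32.4, "O": 21.6, "Si": 37.9},
    "notes": "bolus material; stoichiometry as tabulated (polysiloxane-like)"
  },
  "skin": {
    "density_g_cm3": 1.09,
    "composition_percent": {"H": 10.0, "C": 20.4, "N": 4.2, "O": 64.5, "Na": 0.2, "P": 0.1, "S": 0.2, "Cl": 0.3, "K": 0.1},
    "notes": "0.3 cm layer in every bundled treatment model"
  },
  "soft-tissue": {
    "density_g_cm3": 1.03,
    "composition_percent": {"H": 10.5, "C": 25.6, "N": 2.7, "O": 60.2, "Na": 0.1, "P": 0.2, "S": 0.3, "Cl": 0.2, "K": 0.2},
    "notes": "layers 3 and 4 of the superficial-tumor model"
  },
  "muscle": {
    "density_g_cm3": 1.05,
    "composition_percent": {"H": 10.2, "C": 14.3, "N": 3.4, "O": 71.0, "Na": 0.1, "P": 0.2, "S": 0.3, "Cl": 0.1, "K": 0.4},
    "notes": "layer 3 of the postoperative-breast model"
  },
  "lung": {
    "density_g_cm3": 0.5,
    "composition_percent": {"H": 10.5, "C": 8.3, "N": 2.3, "O": 77.9, "Na": 0.2, "P": 0.1, "S": 0.2, "Cl": 0.3, "K": 0.2},
    "notes": "inflated lung; physiological density range 0.3450-0.7460 g/cm3, 0.5000 used here"
  }
}
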