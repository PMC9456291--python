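{
  "comment": "Stepwise proton and metal association constants (log10, association) for the chelators used in the pipette solutions. NIST-style critical values adjusted to ionic strength 0.15 M; reference temperature 20 C with van't Hoff enthalpies (kJ/mol) for temperature correction. pK_H lists stepwise proton association constants from the most basic site; [MHL] = K_MHL [M][HL].",
  "reference": {"temperature_C": 20.0, "ionic_strength_M": 0.15},
  "ligands": {
    "EGTA": {
      "pK_H": [9.5, 8.85, 2.7, 2.0],
      "dH_H_kJ": [-24.3, -17.8, 0.0, 0.0],
      "metals": {
        "Ca": {"logK_ML": 10.8, "dH_ML_kJ": -33.1, "logK_MHL": 5.25, "dH_MHL_kJ": 0.0},
        "Mg": {"logK_ML": 5.21, "dH_ML_kJ": 21.3, "logK_MHL": 3.37, "dH_MHL_kJ": 0.0}
      }
    },
    "ATP": {
      "pK_H": [6.45, 4.0],
      "dH_H_kJ": [-5.0, 0.0],
      "metals": {
        "Ca": {"logK_ML": 3.8, "dH_ML_kJ": 0.0, "logK_MHL": 1.8, "dH_MHL_kJ": 0.0},
        "Mg": {"logK_ML": 4.1, "dH_ML_kJ": 18.0, "logK_MHL": 2.2, "dH_MHL_kJ": 0.0}
      }
    }
  }
}
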