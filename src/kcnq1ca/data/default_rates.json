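{
  "comment": "Default KCNQ1 gating rates (1/ms at 0 mV) and effective charges. Calibrated in-repo against the isochronal GV, cross-over, HVA and run-down anchors; regenerate with analysis/02_calibrate_gating.py.",
  "temperature_K": 294.15,
  "a1_0": 0.03,
  "b1_0": 0.0007834264314906127,
  "z_a1": 1.4,
  "z_b1": 1.4,
  "a2_0": 0.0035,
  "b2_0": 0.00016131155675575733,
  "z_a2": 0.0,
  "z_b2": 3.0,
  "a2_ca_floor": 0.16,
  "ko1_0": 0.03,
  "kc1_0": 0.01,
  "ko2_0": 0.01,
  "kc2_0": 0.03,
  "w_IO": 0.24454710458900575,
  "z_s": 1.1,
  "a1s_0": 0.004,
  "b1s_0": 0.004,
  "a2s_0": 0.00026304186981629933,
  "b2s_0": 0.0005,
  "kon_RC": 5e-05,
  "koff_RC": 0.008,
  "kon_IC": 0.0008,
  "koff_IC": 0.0008,
  "kon_AC": 2e-05,
  "koff_AC": 0.01,
  "ca_kd": 2.5e-07,
  "ca_hill_n": 1.3,
  "variants": {
    "WT": {},
    "R116L": {},
    "V185M": {
      "activation_scale": 0.7,
      "deactivation_scale": 2.381884132652949
    },
    "P369L": {}
  },
  "ko1_ca_floor": 0.5496830210951665
}
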