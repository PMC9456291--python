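{
  "comment": "Condition-dependent generator settings. Wash-out plateaus for the anchored conditions are solved by analysis/02_calibrate_gating.py so that the analysis pipeline recovers the printed 4-min relative amplitudes; unanchored conditions use the default plateau.",
  "tau_rundown_s": 90.0,
  "tau_wash_s": {
    "none": 60.0,
    "egta_ringer": 60.0,
    "bapta_am": 150.0
  },
  "initial_ca_nM": {
    "none": 100.0,
    "egta_ringer": 30.0,
    "bapta_am": 5.0
  },
  "cam_ca_gain": 10.0,
  "preincubation_rest_mV": -18.0,
  "default_plateau": 0.8,
  "plateaus": {
    "WT|e2=0|cam=0|ca=low|pre=none": 0.8016146059823479,
    "WT|e2=0|cam=1|ca=low|pre=none": 0.8853105472430982,
    "WT|e2=0|cam=0|ca=high|pre=none": 0.8526697076867407,
    "WT|e2=0|cam=0|ca=high|pre=egta_ringer": 1.0,
    "WT|e2=0|cam=0|ca=high|pre=bapta_am": 1.0
  }
}
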