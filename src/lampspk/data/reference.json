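{
  "name": "reference",
  "description": "Reference assay calibrated for the 25-second generation-matrix worked example (100 starting dumbbell copies).",
  "geometry": {
    "seg_F3": 20,
    "seg_F2": 20,
    "seg_F1": 20,
    "seg_B1": 20,
    "seg_B2": 20,
    "seg_B3": 20,
    "spacer_F1F2": 20,
    "spacer_B1B2": 20,
    "spacer_F2F3": 40,
    "spacer_B2B3": 40,
    "core": 40,
    "conc_inner": 1.6,
    "conc_outer": 0.2
  },
  "params": {
    "v": 69.0,
    "branching": {
      "pSS_I": "19/20",
      "pSS_II": "1/40",
      "pSS_III": "1/40",
      "pPDS_I": "1/2",
      "pPDS_II": "1/40",
      "pPDS_III": "19/40"
    },
    "init_self_nt": 400,
    "init_internal_nt": 360
  },
  "worked_example": {
    "n0": 100,
    "t_R_s": 25.0
  }
}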