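{
 "plate": {
  "responses": [
   {"sensor": "DC1", "condition": 1, "channel": "G", "slope": 50.0},
   {"sensor": "DC1", "condition": 2, "channel": "G", "slope": 45.0},
   {"sensor": "DC1", "condition": 1, "channel": "B", "slope": 12.0},
   {"sensor": "DC2", "condition": 1, "channel": "B", "slope": 30.0},
   {"sensor": "DC2", "condition": 2, "channel": "B", "slope": 28.0},
   {"sensor": "DC3", "condition": 1, "channel": "G", "slope": 20.0},
   {"sensor": "DC3", "condition": 2, "channel": "G", "slope": 18.0},
   {"sensor": "DC4", "condition": 1, "channel": "R", "slope": 8.0}
  ],
  "baseline": [180, 140, 160],
  "pixel_noise_sd": 2.0,
  "concentrations_mM": [10, 25, 50, 62.5, 80, 100],
  "seed": 0
 },
 "spectrum": {
  "peaks": {
   "ketamine": {
    "lambda0_nm": 516.0,
    "lambda_slope_nm_per_mM": 0.044444444444444446,
    "a0_AU": 1.05,
    "a_slope_AU_per_mM": -0.004333333333333333,
    "width_nm": 30.0
   },
   "phenylalanine": {
    "lambda0_nm": 516.0,
    "lambda_slope_nm_per_mM": 0.03,
    "a0_AU": 1.37,
    "a_slope_AU_per_mM": -0.0009,
    "width_nm": 30.0
   }
  },
  "noise_sd_AU": 0.01,
  "grid_nm": [400.0, 700.0, 1.0],
  "seed": 0
 }
}
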