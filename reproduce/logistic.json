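{
  "system": "logistic",
  "drive_params": {},
  "surrogate": "logistic",
  "seed": 1,
  "lyapunov": {"min_separation": 0.001, "step_offset": 50, "epsilon": 1e-05,
               "smooth_order": 2, "smooth_frame": 15},
  "otl": {"theta": 0.5, "tau_min": 0.1},
  "xcorr_max_lag": 500
}
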