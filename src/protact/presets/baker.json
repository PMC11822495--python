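{"gain": 0.5, "offset": 0.039, "v_min": -0.27, "v_max": 0.05,
 "lp_cutoff": null, "freq_shift": 0.0, "noise_sd": 0.005, "seed": 0}
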