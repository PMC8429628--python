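{
  "name": "kcsa_e71a_decane",
  "conductance_g": 103.6,
  "reversal_E": 0.0,
  "open_prob": 0.85,
  "mean_open": 100.0,
  "channel_count_lambda": 0.6,
  "noise": {
    "baseline_rms": 0.5,
    "drift_rate": 0.2,
    "spike_rate": 0.02,
    "spike_amplitude": 3.0,
    "lowpass_cutoff": null
  }
}
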