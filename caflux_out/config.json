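{
  "correlation": {
    "signal": "s",
    "tau_max": 5
  },
  "fps": 1.0,
  "frames": [
    "does_not_exist.png"
  ],
  "network": {
    "max_delay_s": 0.5,
    "max_dist_um": 208.0,
    "min_corr": 0.25
  },
  "out_dir": "caflux_out",
  "reference_frame": 0,
  "segmentation": {
    "connectivity": 8,
    "min_size_px": 4,
    "sigma_a": 2.0,
    "sigma_b": 6.0,
    "sigma_n": 1.0,
    "th": 0.1
  },
  "spikes": {
    "influence": 0.5,
    "l": 10,
    "min_spikes": 0,
    "th_r": 0.1,
    "th_z": 5.0
  },
  "um_per_px": 1.0,
  "video": null
}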