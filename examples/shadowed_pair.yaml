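scene:
  targets:
  - range_m: 3.0
    angle_deg: 0.0
    resp_freq_hz: 0.3
    resp_amp: 1.0
    body_thickness_m: 0.45
    resp_phase_rad: 0.0
  - range_m: 6.0
    angle_deg: 0.0
    resp_freq_hz: 0.25
    resp_amp: 1.0
    body_thickness_m: 0.45
    resp_phase_rad: 0.0
  n_fast: 2048
  fast_window_ns: 60.0
  slow_fs_hz: 64.0
  duration_s: 128.0
  wall_range_m:
  - 0.0
  - 1.0
  wall_amp: 2.0
  noise_sigma: 0.1
  shadow_half_angle_deg: 20.0
  shadow_atten: 0.75
  trail_length_m: 1.0
  trail_amp_frac: 0.18
  trail_gap_m: 0.4
  seed: 1
preprocess:
  n_range_bins: 200
  clutter_window: 100
  lp_cutoff_hz: 16.0
  lp_order: 64
autocorr:
  estimator: biased
  max_lag: null
  normalize: false
wavelet:
  wavelet_name: db4
  n_levels: 6
  window_len: null
  energy_mode: mean_per_coeff
  window_combine: mean
  boundary_mode: periodization
detection:
  blind_range_m: 1.0
  pit_k: 3.0
  min_pit_width_m: 0.2
  max_pit_width_m: 0.8
  ghost_window_m: 1.0
  power_k: 8.0
  power_floor_ratio: 2.5
  power_band_hz:
  - 0.1
  - 1.0
out_dir: run1
log_level: INFO
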