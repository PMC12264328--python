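# Scaled-down demo configuration: 10 subjects x 5 repeats, T = 20.
cohort:
  n_per_group: 5
  n_repeats: 5
  grid_shape: [10, 48, 48]
  spacing: [1.458, 1.458, 5.5]
  volume_effect: -0.2
  texture_effect: 0.5
  reposition_sigma: 3.0
  noise_sigma: 6.0
  seed: 1
profiles:
  calibrated:
    band_width: 3.0
    replicate_jitter: 1.8
    calibration: 1.0
    bias: 0.0
  miscalibrated:
    band_width: 3.0
    replicate_jitter: 1.8
    calibration: 0.2
    bias: 0.0
T: 20
thresholds: [10, 20, 30, 40, 50, 60, 70, 80, 90, 100]
icc_cutoff: 0.8
n_boot: 500
n_selected: 5
seed: 1
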