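# Default system configuration (C1 sensor, 3 mm lens, 1 m baseline)
sensor_catalog:
  C1:
    vsr_h: 3280
    vsr_v: 2464
    vss_h: 3.68
    vss_v: 2.76
  C2:
    vsr_h: 4056
    vsr_v: 3040
    vss_h: 6.287
    vss_v: 4.712
  C3:
    vsr_h: 4208
    vsr_v: 3120
    vss_h: 6.3
    vss_v: 5.7
  C4:
    vsr_h: 4912
    vsr_v: 3684
    vss_h: 7.66
    vss_v: 4.56
assembly:
  sensor: C1
  f_mm: 3.0
rig:
  baseline: 1.0
  vsr_axis: 3280
  fov_axis_deg: 63.0
  tilt_alpha_deg: null
detection:
  blur_kernel: 5
  blur_sigma: 1.5
  diff_thresh: 25
  merge_kernel: 9
  merge_sigma: 2.0
  binary_thresh: 100
  min_w: 12
  min_h: 2
  crop_size: 100
cnn:
  lc1: 32
  lc2: 32
  lfc1: 128
  n_classes: 2
  kernel: 3
  pool: 2
  learning_rate: 1.0e-05
  adam_epsilon: 1.0e-07
  epochs: 50
  validation_split: 0.1
  batch_size: 32
classes:
  wingspan:
  - 0.68
  - 1.26
  - 1.505
  height:
  - 0.32
  - 0.4
  - 0.555
  area:
  - 0.11
  - 0.25
  - 0.415
policy:
  strobe:
    small: 300.0
    medium: 300.0
    large: 300.0
  audio:
    small: 300.0
    medium: 300.0
    large: 300.0
  turbine_stop:
    large: 200.0
matching:
  max_center_offset_px: 150.0
  min_disparity_px: 1.0
  sync_tolerance_s: 0.05
paths:
  archive: events
  media: media
seed: 0
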