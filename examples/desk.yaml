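geometry:
  detector_side: 32
  pixel_pitch_um: 886.875     # 55 um * 516/32: same field of view as production
  beamstop_radius_px: 2
  gap_width_px: 0
phantom:
  scale: 0.09                 # ~0.36 um desk-scale cell
  grid_side: 32
  voxel_size_nm: 30.0
  texture_amplitude: 0.05
  total_electrons: 5.0e10
acquisition:
  n_positive: 37
  n_negative: 34
  max_angle_deg: 50.9
  max_angle_negative_deg: 60.6
  poisson_noise: true
reconstruction:
  n_iterations: 300
  n_seeds: 5
  keep_best: 2
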