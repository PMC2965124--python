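# Small-scale demonstration run: tube phantoms, 6-node motor network, n=12/12 cohort.
out_dir: motornet_demo
phantom:
  grid_shape: [16, 16, 36]
  voxel_size: 2.0
  radius_mm: 4.0
  fa_start: 0.5     # planted FA at the cortex end of the patient tract
  fa_end: 0.7       # ... rising toward the brainstem end
  control_fa: 0.7   # flat control profile
  background_fa: 0.05
  s0: 1000.0
  noise_sigma: 0.0
tracking:
  seed_fa: 0.2
  stop_fa: 0.2
  max_angle_deg: 45.0
  min_length_mm: 10.0
bold:
  n_timepoints: 960   # 8 min at 0.5 s sampling
  dt: 0.5
  noise_frac: 0.1
  within_r: 0.55
  between_r: 0.35
  homotopic_r: 0.55
  patient_between_r: 0.25
  patient_homotopic_r: 0.45
filter:
  low_hz: 0.01
  high_hz: 0.1
graph:
  thresholds: [0.3, 0.4]
  n_random: 100
cohort:
  n_per_group: 12
profile_points: 100
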