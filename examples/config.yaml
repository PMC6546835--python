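# Full pipeline configuration: two gel-density conditions with time-lapse.
seed: 1
output_dir: out
n_replicates: 3
roi:
  side_length: 700
  bin_width: 100
thresholds:
  overlap_fraction: 0.5   # dead-stain overlap needed to call a target dead
  onset_fraction: 0.3     # dead-stain overlap marking uptake in time lapse
  persistence: 2          # frames the uptake must persist
  contact_dilation: 1     # px dilation for the contact test
  min_area: null          # null -> 25% of calibrated mean live target area
  max_step: 20.0          # μm, tracking gate
  blank_guard: 0.45       # foreground fraction treated as a blank channel
scene:
  field_size: [700.0, 700.0]
  pixel_size: 2.0
  n_target_cells: 120
  dead_fraction: 0.3
  n_effector_cells: 300
  infiltration_decay_length: 250.0
timelapse:
  n_frames: 40
  frame_interval: 5.0
  effector_step_sd: 5.0
  contact_distance: 4.0
  kill_probability_per_contact: 0.8
  pi_delay_mean: 30.0
  pi_delay_sd: 6.0
conditions:
  - label: sparse_gel
    scene: {infiltration_decay_length: 300.0, n_effector_cells: 150}
  - label: dense_gel
    scene: {infiltration_decay_length: 60.0, n_effector_cells: 120}
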