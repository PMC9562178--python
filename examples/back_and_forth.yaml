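name: bf-demo
field:
  plants_per_lane: 20
  in_lane_spacing_mean: 100.0
  in_lane_spacing_jitter: 10.0
  box_w_mean: 80.0
  box_h_mean: 80.0
  box_size_jitter: 6.0
  seed: 0
motion:
  regime: back_and_forth
  n_frames: 200
  dy: 6.0
noise:
  center_sigma: 2.0
  size_sigma: 2.0
  p_miss: 0.05
  seed: 100
tracker:
  association:
    x1: 14
    x2: 14
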