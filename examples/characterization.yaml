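scenario: characterization
camera: cmos
seed: 1
params:
  roi: [64, 64]
  n_dark_frames: 4000
  n_levels: 15
  frames_per_level: 2000
  hot_fraction: 0.0011
  warmup_minutes: 90
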