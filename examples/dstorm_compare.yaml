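scenario: dstorm_compare
camera: cmos
camera_b: scmos
seed: 1
params:
  roi: [40, 40]
  n_frames: 1200
  n_emitters: 600
  on_probability: 0.003
  drift_bins: 3
  label_scatter_nm: 15.0
  photons: {dist: lognormal, median: 5000.0, sigma: 1.0}
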