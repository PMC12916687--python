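# Desk-scale end-to-end configuration: one CPU core, minutes of runtime.
# `msgm run --simulate --config configs/small.yaml --out runs/small`
seed: 1
simulation:
  n_subjects: 8
  trials_per_subject: 4
  c: 16
  fs: 128.0
  duration_s: 44.0
  classes: [low, high]
  effect_band: alpha
  effect_size: 1.0
  n_regions: 4
  within_region_corr: 0.6
  noise_exponent: 1.0
segmentation:
  window_s: 20.0
  hop_s: 4.0
  scales: [[4.0, 2.0], [8.0, 4.0]]
model:
  h: 32
  M: 1
  cheb_order: 3
  w_out: 8
  d_state: 16
  conv_kernel: 4
  dropout: 0.25
  feature_type: rpsd
training:
  lr: 0.0003
  batch_size: 32
  epochs: 15
  patience: 5
  protocol: loso
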