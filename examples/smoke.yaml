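# Desk-scale end-to-end run on phantom data (single CPU, ~2 min)
out_dir: runs/smoke
seed: 7
phantoms:
  n_volumes: 5
  n_slices: 10
  image_size: 32
localizer:
  window_length: 5
  normalization: MaxMinNorm
  hidden_channels: 4
  kernel_size: 3
  epochs: 8
  lr: 0.05
seg_train:
  epochs: 10
  lr: 0.01
  batch_size: 8
segmenter:
  use_mr: true
  use_attn: true
  depth: 4
  base_channels: 16
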