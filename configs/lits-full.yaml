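# Full-scale two-stage configuration (LiTS-style data, long training).
# Use with:  hepaseg train --stage liver --config configs/lits-full.yaml ...
network:
  levels: 4
  stage_channels: [62, 130, 158, 248]
  use_elanres: true
  use_msca: true
  elan_units: 4
  elan_hidden: [74, 156]
  msca_blocks: 2
  msca_attn_channels: 412
  msca_mlp_channels: 872
  head_hidden: 67
  ds_heads: 4
  deploy: false
train:
  lr0: 1.0e-4          # reduced by 20% every 30 epochs
  lr_decay: 0.8
  lr_decay_period: 30
  epochs: 200
  steps_per_epoch: 250
  batch_size: 2
  patch_size: [160, 160, 64]
  foreground_oversample: 0.5
  loss_name: hybrid1
  split_ratio: "3:1"
  roi_margin: 10
  seed: 0
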