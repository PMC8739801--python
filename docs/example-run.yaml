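# Example configuration for `erj run --config docs/example-run.yaml`.
# A synthetic image fixture stands in for a class-per-directory image
# folder; replace `fixture:` with `folder: /path/to/images` for real data.
data:
  fixture:
    n_classes: 3
    modes_per_class: 4
    samples_per_class: 100
    hidden_modes_per_class: 1
    duplication_rate: 0.3
    level: image
    image_shape: [16, 16]
  train_fraction: 0.8          # 8:2 train/test
  base_fraction_of_train: 0.1  # 1:9 base/pool
extractor:
  preset: tiny                 # tiny | shallow | middle | deep
  input_shape: [16, 16, 3]
selection:
  strategy: hard_first         # hard_first | easy_first | bad_data | random
  quota: 8                     # per class per round (full-scale default: 40)
loop:
  rounds_max: 3
  retrain_mode: cold
  epochs_per_round: 80
out_dir: erj_out
seed: 7
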