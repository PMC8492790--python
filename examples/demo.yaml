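# Minimal demonstration run: 2 source subjects + 1 target, reduced epochs.
# Finishes in a few minutes on one CPU; outputs land in runs/demo/.
seed: 1
out_dir: runs/demo
synth:
  n_channels: 32
  n_trials: 60
train:
  epochs: 40
cohort:
  n_source_subjects: 2
  n_target_subjects: 1
  difficulty_profile: hard
evaluation:
  n_repeats: 3
  n_train: 40
  plans: [EEGNet_0, EEGNet_1, EEGNet_2]
  baselines: [svm, lda]
  finetune_epochs: 30
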