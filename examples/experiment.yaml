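# A small early→delayed PET translation experiment on the kinetic phantom.
out_dir: runs/demo
seed: 7
phantom:
  n_subjects: 8
  n_slices: 20
  slice_shape: [32, 32]
split: {train: 5, val: 1, test: 2}
times: {t_early: 14.0, t_late: 52.0}
loss: lsgan+l1
train:
  epochs: 12
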