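# Default demonstration configuration: a small decodable synthetic
# experiment (4 lists, two bipolar contacts, 3x high-gamma burst-rate
# effect for recalled words) run end to end in a couple of minutes.
run_dir: runs/demo
seed: 7
simulate:
  n_lists: 4
  n_channels: 2
  fs_hz: 500
  recall_p: 0.4
  hg_effect: [3.0, 1.0]
  beta_effect: [1.0, 1.0]
  line_amp_uv: 2.0
detect:
  z_thresh: 2.0
tensorize:
  tensor_fs: 20.0
  window_s: 3.0
  per_list: 12
train:
  model: cnn2b
  epochs: 30
  folds: 5
glm:
  n_simulated: 62
explain:
  n_segments: 10
  n_samples: 0
  trials: 8
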