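# Default parameters for the six regression families.
PLS:
  n_components: 2
  max_iter: 500
  tol: 1.0e-06
  scale: true
SVM:
  kernel: poly
  degree: 3
  cache_size: 200
  tol: 1.0e-03
  max_iter: -1
  C: 1.0
RF:
  n_estimators: 200
  n_jobs: 1
  min_samples_leaf: 5
  max_samples: null       # bootstrap fraction 1.0
BP:
  hidden_units: 32
  batch_size: 64
  epochs: 400
  learning_rate: 0.01
  goal: 1.0e-05
  solver: sgd
CNN:
  normalize: l2
  optimizer: adam
  activation: relu
  batch_size: 64
  learning_rate: 0.001
  epochs: 400
  dropout: 0.5
  channels: [16, 32, 64]
  kernel_size: 3
  pool_size: 2
LSTM:
  normalize: l2
  optimizer: adam
  activation: tanh
  hidden_units: 20
  batch_size: 64
  learning_rate: 0.001
  epochs: 40
  dropout: 0.5
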