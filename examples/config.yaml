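# Experiment configuration for `hho-featsel run -c examples/config.yaml`.
# Every key is optional; the values below are the defaults unless noted.

data:
  kind: synthetic        # synthetic | arff | csv (then give `path: ...`)
  n_rows: 1151
  class_balance: 0.531   # positive fraction of the real screening table
  effect_size: 1.0       # planted signal strength, in column SDs
  seed: 0

variants: [raw, pca, pca_hho]
models: [dnn, dt, knn, nb, svm, xgboost]

train_fraction: 0.8      # single stratified holdout
split_seed: 0
pca_threshold: 0.99      # retain 99% of the variance

# HHO subset search (fast schedule; the wrapper fitness is penalized CV error)
hho_pop_size: 10
hho_max_iter: 30
hho_seed: 0
fitness:
  estimator: knn
  cv_folds: 5
  penalty_alpha: 0.01
  seed: 0

# Dense network; omit to use the schedule implied by `paper_scale`
# (50 epochs fast / 600 epochs paper-scale).
dnn:
  hidden_layers: [64, 32, 16, 8, 4]
  hidden_activation: softsign
  optimizer: adam
  epochs: 50
  batch_size: 64
  seed: 0

paper_scale: false
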