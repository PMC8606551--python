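# Demo configuration for `reentryforge pipeline --config ...`
# Small enough to complete in a couple of minutes on one CPU.
seed: 7
outdir: runs/demo
population:
  n_patients: 4
  nx: 60
  ny: 60
  spacing: 0.25
  peel_set: [1, 2]
ml:
  n_runs: 10
  models: [knn, svm, logistic, tree, xgboost, nn3, nn4]
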