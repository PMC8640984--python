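# Bundled small synthetic suite: 3 datasets spanning the three SNR regimes,
# n=400 samples x p=60 variables, 50 predictors per experiment,
# n_train in {25, 75}, 5 replicates, both CV routines.
out_dir: scratch/small_suite
synthetic:
  n_datasets: 3
  regimes: [high, intermediate, low]
  n_samples: 400
  n_variables: 60
n_predictors: 50
n_train_values: [25, 75]
replicates: 5
cv_routines: [5, 10]
alpha: 0.05
seed: 20260920
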