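# Config-driven run of the full pipeline on a simulated cohort.
#   confoundcv all --config examples/experiment.yaml --seed 0 --out run1/
simulation:
  n_subjects: 1340
  n_features: 100
  n_informative: 20
  effect_size_d: 0.5
phenotype:
  mode: final_score        # or: slope (threshold the per-subject trajectory)
correction: over           # none | regression | under | over
model:
  families: [logistic, rbf-svm]
cv:
  outer_folds: 7
  inner_folds: 5
  holdout_fraction: 0.2
n_perm: 199
n_holdout_seeds: 7
attribution:
  n_background: 32
  n_targets: 64
  n_orderings: 1
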