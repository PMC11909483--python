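# Full-size synthetic run with the default study conditions.
# Swap `generator` for an `inputs` block naming the four CSV tables
# (baseline/arms/usage/followup) to analyze an existing dataset.
seed: 1
output_dir: results
generator:
  n: 1319
  seed: 1
analysis:
  estimator_mode: tmle        # or "aipw" for the cross-check estimator
  truncation: 0.01            # response-propensity floor
  mi_m: 10                    # imputations for 12-month-only completers
  mi_k: 5                     # predictive-mean-matching donors
  outer_folds: 10             # nested cross-validation, outer loop
  inner_folds: 10             # ... inner loop (ensemble weights)
  top_fraction: 0.40          # predicted-compliance dichotomization
  shap_budget: 512            # sampled coalitions for the attribution
  learner_library: default    # or "linear" for a fast small library
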