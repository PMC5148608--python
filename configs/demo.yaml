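# Demo pipeline: synthetic session from model 2 (distinct gamma/beta gains,
# one shared lag and dead time), 30 trials, 5% force measurement noise.
simulate:
  n_trials: 30
  true_model_id: 2
  noise_sd: 0.05
  seed: 1
pair: auto
feature_rate: 100
models: [2]
cv: "kfold:5"
seed: 7
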