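# gripdecode

Decoding the temporal profile of gripping force from subthalamic-nucleus
local field potentials (LFPs), as a fully testable pipeline:

* **`gripdecode.synthetic`** — session generator with known ground truth:
  movement-locked beta-power suppression and gamma-power increase scaling
  with self-rated effort (SRE, 0–10), a 1/f background plus a common-mode
  artifact shared across the four electrode contacts, and a force channel
  produced by driving a known first-order lag + dead-time model with the
  band-power envelopes.
* **`gripdecode.features`** — bipolar derivation (pairs 01/12/23), Morlet
  CWT (7 cycles, 1–90 Hz), relative power change against the pre-cue
  second, theta/alpha (4–12 Hz), beta (13–30 Hz) and gamma (55–90 Hz) band
  traces, channel selection by deepest beta suppression, the percentile
  modulation-significance rule, epoching to the decode window
  [−1, 2.8] s, force normalisation and force yank.
* **`gripdecode.models`** — eight first-order dynamic models with dead time
  (`Kp / (Tp·s + 1) · e^(−Td·s)` per branch) mapping band power to force:
  gamma−beta difference, separate gains with shared lag, independent
  branches, variants with theta/alpha, and single-band models.  Exact ZOH
  forward simulation, an independent RK4 time-domain oracle, and bounded
  multi-start least-squares identification.
* **`gripdecode.evaluation`** — effort-split (SRE ≤ 5 vs > 5) and k-fold
  cross-validation, WithinTrialR, nRMSE, stable-force correlation, DifRT,
  BIC = n·ln(σe²) + k·ln(n), Fisher z, SRE-scaling Spearman correlations
  and the exponential performance-vs-modulation fit.
* **`gripdecode.cli`** — `simulate`, `features`, `fit`, `evaluate`, `run`,
  `validate` subcommands over plain-text session containers.

## Command line

```bash
# generate a demo session, extract features, cross-validate model 2
gripdecode run --config configs/demo.yaml --out results/demo --seed 1

# or stage by stage
gripdecode simulate --out session/ --seed 1
gripdecode validate --in session/
gripdecode features --in session/ --pair auto --out features.csv
gripdecode fit --features features.csv --model 2 --out params.json
gripdecode evaluate --features features.csv --models 1,2,3,4,5,6,7,8 \
    --cv kfold:5 --seed 7 --out results/
```

A session directory holds `signals.tsv` (time, 4 contacts, force),
`events.csv` (`cue_time_s`, `sre`), `meta.json` and — for synthetic
sessions — `ground_truth.json` plus `true_envelopes.tsv`.  Feature tables
are long-format CSVs (one row per trial × time point); band-power values
are fractional changes (0 = baseline, +1 = doubling) and are converted to
percent only for display.

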