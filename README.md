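# actiplace

Evaluate wearable-accelerometer placements for activity recognition and
energy-expenditure estimation.

The package implements a complete, seeded evaluation pipeline for the
question "how many accelerometers, and where, are needed?":

1. **`actiplace.synth`** — simulate a cohort of participants wearing five
   triaxial accelerometers (ankle, upper arm, hip, thigh, wrist; 100 Hz,
   units of g) while performing scripted activities from three mutually
   exclusive categories (sedentary / locomotion / lifestyle), together with
   breath-by-breath VO2 traces that plateau at each session's metabolic
   level about two minutes after activity onset. Everything derives from a
   single cohort seed, so cohorts are bit-reproducible.
2. **`actiplace.features`** — segment each recording into contiguous
   16-second windows and compute 15 summary features per window and
   placement: mean/SD of the vector magnitude (VM), mean/SD of the angle
   between the x-axis and the VM, lag-1 autocovariance, skewness, excess
   kurtosis, histogram entropy, coefficient of variation, the three axis
   correlations, the fraction of spectral moduli in 0.6–2.5 Hz, the
   dominant frequency, and the modulus fraction at the dominant frequency.
3. **`actiplace.metabolic`** — convert VO2 traces to session-level MET
   labels: 30-s running-average smoothing, discard the first 120 s
   (non-steady-state onset), divide the plateau mean by the
   3.5 mL·min⁻¹·kg⁻¹ resting convention. Traces too short for a plateau
   are excluded and counted.
4. **`actiplace.experiment`** — enumerate the 31 non-empty placement
   combinations (codes A: ankle, B: upper arm, C: hip, D: thigh,
   E: wrist), build participant-exclusive nested cross-validation plans
   (default 6 outer folds = 5/6 development + 1/6 test; 5 inner folds for
   hyperparameter tuning), and run random forests for five tasks: three
   binary category detections (scored by balanced accuracy), individual
   activity recognition (accuracy), and MET regression (RMSE).
5. **`actiplace.evaluation`** — metrics, 32×32 confusion matrices,
   difference-vs-all-five-placements ranking tables, and the guideline
   rule that picks the *most efficient* combination: combinations within a
   similarity margin of the best are ranked either fewest-sensors-first
   (literal reading) or usability-first (wrist > hip > ankle > upper arm >
   thigh, judging a combination by its most burdensome member). Both the
   margin mode (`relative` / `absolute`) and the rule are configurable
   because the published selection table is not reproducible under a
   single literal margin convention.

## Command-line pipeline

Each stage reads and writes a shared working directory:

```sh
actiplace simulate   --config config.yaml --out run/ --seed 1
actiplace features   --config config.yaml --out run/ --seed 1
actiplace met        --config config.yaml --out run/ --seed 1
actiplace experiment --config config.yaml --out run/ --seed 1
actiplace report     --config config.yaml --out run/ --seed 1 \
    --margin 0.10 --margin-mode relative
```

Outputs: per-session raw CSVs plus a checksummed manifest (`simulate`),
the windowed feature table (`features`), MET labels with exclusion counts
(`met`), per-cell metrics and prediction records (`experiment`), and
ranking tables plus the guideline CSV (`report`). A YAML config can
override any default (cohort size, roster composition, window length,
onset rule, CV folds, forest grid, selection margin); the CLI `--seed`
pins every source of randomness. Reruns with the same config and seed are
idempotent, and the experiment stage resumes from its per-cell store.

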