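# ctgeval

Cardiotocography (CTG) analysis toolkit: fetal-heart-rate signal cleaning,
guideline-style feature extraction, neonatal asphyxia outcome labeling,
human/AI prediction fusion, and diagnostic-accuracy evaluation — plus a
seeded synthetic cohort generator so the whole chain runs without clinical
data.

## What it does

- **`ctgeval.io`** — trace CSVs (4 Hz FHR + uterine-contraction channel,
  `# key: value` header block), cohort tables (outcomes / rater responses /
  model scores), 2x2 confusion-matrix fixtures, YAML run config. Masked FHR
  samples serialize as empty fields; a literal 0 is raw transducer dropout.
- **`ctgeval.preprocess`** — the cleaning chain: discontinue at the first
  ≥15 s zero run, mask remaining zeros and values ≥200 / ≤50 bpm, mask
  samples deviating >25 bpm from their 15 s window mean, linearly
  interpolate everything masked, smooth UC with a centered 60 s moving
  average, then cut the 30-minute segment ending 20 minutes before delivery
  (exactly 7200 samples).
- **`ctgeval.features`** — a documented 44-descriptor vector (baseline,
  variability, accelerations, typed decelerations, contraction context);
  the roster lives in `feature_manifest.yaml`.
- **`ctgeval.judgments`** — outcome labeling (Apgar <6 at 1 or 5 min, or
  umbilical-artery pH <7.1), rater prediction ratios, 0.50 score cutoff,
  additive and multiplicative human x model fusion.
- **`ctgeval.diagnostics`** — confusion matrices, the five percent metrics
  (half-up rounding to 2 decimals), likelihood ratios, ROC curves with
  midrank tie handling, Hanley–McNeil AUC significance.
- **`ctgeval.synthetic`** — seeded generators for clean traces with a
  ground-truth event ledger, artifact injection (with an exact corruption
  ledger), logistic outcome model, reader-panel simulation, and a full
  study cohort with an exact positive count.

## CLI

```sh
ctgeval simulate --n 489 --n-pos 31 --seed 1 --out cohort/ [--traces]
ctgeval clean raw_trace.csv cleaned.csv            # + JSON removal sidecar
ctgeval features trace1.csv trace2.csv --out features.csv
ctgeval score --outcomes cohort/outcomes.csv --ratings cohort/ratings.csv \
              --scores cohort/scores.csv --out predictions.csv
ctgeval evaluate --predictions predictions.csv --out eval/
ctgeval evaluate --confusion-csv fixture.csv --out eval/
```

`simulate` accepts a YAML `--config` with `trace`, `artifacts`, `raters`,
and `scores` sections mapping onto the parameter dataclasses; `score` and
`evaluate` read decision cutoffs from a `decision` section.

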