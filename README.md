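# broilerweight

Non-invasive broiler live-weight estimation as a tested, reusable
pipeline, exercisable entirely on synthetic data. The package covers:

- **`synthetic_data`** — virtual cohorts of broilers (default: 100 birds,
  50/50 male/female, 42 daily records each = 4200 records): Richards
  growth trajectories with bird- and day-level noise, allometric back
  length/width, pixel areas consistent with the log-pixel regression
  structure, and rendered top-view images with exact ground-truth masks.
- **`growth_model`** — the Richards growth function
  `LW(t) = A(1 + B e^{-kt})^{-1/m}`: evaluation and multi-start
  nonlinear least-squares fitting with R²/RMSE/MAPE diagnostics.
- **`image_pipeline`** — four-step vision workflow: ROI detection via
  the black 600×400 mm reference floor, Otsu segmentation of the bird
  inside the ROI, foreground pixel counting, QC overlay export, and
  5-replicate averaging.
- **`pixel_regression`** — OLS fit of
  `logLW = b0 + b1·Day + b2·logP + b3·(Day×logP)` (base 10 by default,
  base recorded in the model artifact), back-transformed metrics in
  grams, and weekly (7-day band) RMSE/MAPE stratification.
- **`ml_benchmark`** — evaluation protocol for five regressors
  (random forest, gradient-boosted trees, SVR, KNN, multiple linear
  regression) predicting live weight from back length/width: min–max
  scaling fitted on training data only, record-level 80/20 splits
  stratified by age band, grid-search CV on a 90% tuning subset,
  10-repeat random sub-sampling, and exact two-feature Shapley
  attribution.
- **`metrics`** — R², RMSE and MAPE with population denominators.

## CLI

A single `broilerweight` entry point with subcommands:

```bash
# generate a cohort (records.csv; --images also renders PNGs + masks)
broilerweight simulate --out-dir out/ --seed 1 [--config cohort.yaml] [--images]

# fit the Richards growth curve to pooled group data
broilerweight fit-growth --records out/records.csv --group male --out fit.json

# segment a directory of top-view images (filenames <bird>_<day>_<rep>.png)
broilerweight segment --images out/images --out counts.csv [--overlays qc/]

# fit the log-pixel regression on an 80/20 record-level split
broilerweight fit-pixel-model --records out/records.csv --group mixed \
    --split-seed 1 --out model.json --weekly-out weekly.csv

# predict live weight (g) from day and pixel area
broilerweight predict --model model.json --day 21 --pixels 60000

# run the repeated ML benchmarking protocol
broilerweight benchmark --records out/records.csv --dataset mixed \
    --repeats 10 --seed 1 --out report/
```

YAML passed via `simulate --config` overrides `CohortConfig` fields
(e.g. `n_birds: 20`).

## Notes

- Gradient-boosted trees use scikit-learn's `GradientBoostingRegressor`
  (key `gbt`) with a learning_rate/max_depth/n_estimators/subsample
  grid.
- Logarithm base for the pixel regression defaults to 10 and is stored
  in every model artifact; base *e* is supported.
- Rendered birds are elliptical blobs on a near-black floor; the vision
  pipeline depends only on contrast with the floor, not on silhouette
  shape.
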