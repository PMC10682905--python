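# nichekit

Ecological niche modelling and niche-comparison toolkit. It implements, as a
tested and reusable pipeline, the comparative analysis of environmental niches
across occurrence classes (e.g. a domestication gradient
wild → semiwild → landrace → commercial):

- **grids** — raster data model (single-band GeoTIFF / ESRI ASCII grid I/O,
  co-registration checks, convex-hull cropping with a buffered model area).
- **synthdata** — seeded synthetic worlds: correlated bioclim-like layers,
  Gaussian true niches with controllable nesting, occurrence sampling,
  polygon proxy points, and pseudo-GCM future scenario suites
  (3 periods × 2 pathways × 8 GCMs by default).
- **occurrences** — occurrence CSV model, greedy 5-km spatial thinning
  (haversine), half-open-rule environmental extraction, greedy
  correlation-based variable pre-selection, seeded train/test splits.
- **envspace** — standardized PCA, minimum convex hull envelopes in PC1–PC2,
  area- and point-density-based hull overlap, percentile bootstrap CIs and
  compact letter displays.
- **maxent** — from-scratch presence–background maximum-entropy model
  (LQHP features, per-feature-class L1 penalties, monotone proximal gradient
  ascent, clamping, entropy-based logistic output), AUC/TSS, permutation
  importance, jackknife, replicated 70/30 cross-validation with median/SD maps.
- **overlap** — Schoener's D, Warren's I and Spearman ρ between suitability
  surfaces, niche equivalency and background randomization tests, and the
  occupancy-grid environment-space overlap variant.
- **futures** — training-score percentile thresholds, loss/gain/retention
  change accounting, all-GCM intersection/union, between-class overlap change,
  and MESS (multivariate environmental similarity) transferability surfaces.
- **pipeline / cli** — one-config orchestration of the whole analysis with
  fully deterministic, seed-fanned outputs.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: exact formula
oracles, synthetic-recovery checks for the maxent fitter, qualitative
pattern recovery on the nested niche design, futures accounting
identities, statistical calibration, and byte-identical rerun determinism.

## CLI

```sh
nichekit simulate --seed 1 --outdir runs/sim          # synthetic world
nichekit thin runs/sim/occurrences.csv --min-dist-km 5 --out thinned.csv
nichekit extract thinned.csv runs/sim/bio*.asc --out extracted.csv
nichekit pca extracted.csv --out-prefix runs/pca
nichekit envelope runs/pca_scores.csv --out hulls.csv
nichekit fit thinned.csv runs/sim/bio*.asc --out model.lambdas.txt
nichekit overlap mapA.asc mapB.asc
nichekit mess extracted.csv future_bio*.asc --out mess.asc
nichekit run-all --seed 1 --outdir runs/full          # whole pipeline
nichekit run-all --seed 1 --outdir runs/quick --small # desk-scale variant
```

Exit codes: 0 ok, 1 input error, 2 internal error.

## Conventions

- Grids are top-left-origin, row-major, y decreasing with row index; a cell's
  location is its center; cells are assigned by the half-open rule
  (x ∈ [left, right), y ∈ (top, bottom]).
- "Area" is unmasked-pixel count (a cos-latitude-weighted variant is
  available via `grids.pixel_area`).
- Geometry equality tolerance is 1e-9 degrees; mismatched stacks are a hard
  error (no resampling).
- All randomness flows from a master seed through fixed per-stage offsets
  (`synthdata.SEED_OFFSETS`), recorded in each run manifest.
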