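# vesselage

Intracranial vessel morphometry and age-prediction pipeline for 3D
angiography volumes. From a NIfTI volume and two endpoint annotations per
vessel segment, the package extracts six tortuosity descriptors and seven
diameter statistics per segment (39 features per subject over the R-ICA,
L-ICA and BA segments), and trains/evaluates six regression models for age
with four-fold cross-validation. A synthetic vascular-phantom generator
provides ground-truth data for every stage, so the whole pipeline is
testable without any external cohort.

## Stages

| module | role |
| --- | --- |
| `vesselage.phantom` | parametric curves (straight/helix/sinusoid/siphon), tube rasterization onto anisotropic grids, tabular cohorts with a known linear age model, full three-segment volumetric subjects — all with ground truth and an independent tortuosity oracle |
| `vesselage.segmentation` | seeded region growing with an absolute or percentile intensity threshold (6/26-connectivity) |
| `vesselage.centerline` | 3D skeletonization, 26-adjacency skeleton graph with mm edge weights, Dijkstra path between annotated endpoints, smoothing-spline + uniform arc-length resampling, numeric path QC |
| `vesselage.morphometry` | curve length, Euclidean length, relative length (RL), sum of angle metrics (SOAM, degrees/mm), product of angle distance (PAD = SOAM/RL by default, switchable), triangular index (TI), and distance-transform diameters with seven summary statistics |
| `vesselage.cohort` | exclusion logic, the canonical 39-column modeling table and its CSV schema (optional `.xlsx` export) |
| `vesselage.modeling` | six model families (random forest, linear, AdaBoost, gradient boosting, Bayesian ridge, and an xgb-style regularized boosted ensemble), k-fold CV, Pearson r / RMSE / MAPE / R² metrics, impurity feature importances, scatter plots |
| `vesselage.pipeline` / `vesselage.cli` | end-to-end orchestration with a manifest, plus per-stage CLI subcommands |

## CLI

Every stage is independently invocable; `--help` documents each command.

```sh
# self-contained demonstration: 12 phantom subjects through the whole pipeline
vesselage demo --seed 1 --n-subjects 12 --out runs/demo

# individual stages
vesselage phantom --kind volumetric --age 60 --seed 0 --out runs/sub0
vesselage segment --in runs/sub0/volume.nii.gz --seed 80,32,18 \
    --threshold 125 --out runs/sub0/mask.nii.gz
vesselage centerline --mask runs/sub0/mask.nii.gz \
    --annotations runs/sub0/endpoints.json --step 0.5 --out runs/sub0/centerlines.json
vesselage features --mask runs/sub0/mask.nii.gz \
    --centerlines runs/sub0/centerlines.json --out runs/sub0/features.json
vesselage train --table cohort.csv --families linear,random_forest --out results/

# full run from a YAML config (see PipelineConfig.from_yaml for the schema)
vesselage run --config pipeline.yaml
```

A run directory contains `masks/`, `centerlines/`, `cohort.csv`,
`exclusions.json`, `metrics.csv` / `metrics_table.csv`, `importances.csv`,
`predictions.csv`, `plots/` and a `manifest.json` recording the seed,
configuration and per-subject QC outcomes. Runs are deterministic under a
fixed seed.

## Conventions worth knowing

* Angles are in degrees; SOAM and PAD are degrees/mm.
* PAD defaults to the quotient reading SOAM/RL (`pad_definition`
  switches to the product reading).
* Diameters are twice the anisotropy-aware Euclidean distance transform at
  the voxel containing each resampled centerline point; percentiles use
  linear interpolation and the standard deviation is the population form.
* Voxel indices are 0-based; a voxel's physical position is
  `origin + index * spacing` (no orientation-matrix handling).
* Feature columns are named `{segment}_{suffix}` (e.g. `R-ICA_diam_mean`),
  ordered R-ICA, L-ICA, BA blocks of 13.
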