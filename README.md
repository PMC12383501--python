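# tropicatch

Thermal-affinity indicators and community-composition analysis for
pelagic catch time series.

Given annual catch records (year, species, region, tonnes), a table of
species thermal preferences, and annual environmental series, the
package computes:

- **MTC** — the mean temperature of the catch (catch-weighted mean of
  species' preferred temperatures), warm-fraction series, and anomaly
  series (`thermal_mtc`);
- **trend models** — OLS linear trends, penalized cubic regression
  splines (k = 5, GCV-selected smoothness) with an all-criteria model
  choice rule, ANCOVA slope comparison between regions,
  leave-one-species-out sensitivity of the MTC trend, and 0–4 year
  lagged driver models selected by AIC / R² / slope significance
  (`trend_models`);
- **composition** — Hellinger transform, Hellinger and
  percentage-difference distance matrices, a chronological multivariate
  regression tree with cross-validated size selection, and principal
  coordinates ordination (`composition`);
- **beta diversity** — total beta diversity (SStotal / (n−1)) with
  species (SCBD) and year (YCBD) contributions, a 999-permutation test
  of YCBD, and temporal beta-diversity indices decomposed into biomass
  gains and losses with a paired t-test (`beta_diversity`);
- **synthetic data** — seeded scenario generators with planted
  tropicalization signals, so every stage is testable without external
  data (`synthetic_data`);
- **I/O and orchestration** — validated record ingestion with a
  two-sector regional split, and a config-driven pipeline/CLI
  (`catch_io`, `cli_pipeline`).

## CLI

All commands read a YAML config:

```yaml
output_dir: out/
seed: 1
regions: [SWAO, SEAO]          # SWAO = study box west of 20W, SEAO = east
simulate:                      # exactly one of `simulate` or `inputs`
  preset: tropicalization      # or `null`, or explicit ScenarioParams fields
  n_years: 41
  n_species: 29
  warm_fraction: 0.5517        # 16/29
# inputs:
#   catch: catch.csv           # year,species_code,...,lat,lon,catch_tonnes
#   thermal: thermal.csv       # species_code,t_pref_c
#   sst: sst.csv               # year,value
#   bct: bct.csv               # year,value
#   study_window: [1978, 2018]
threshold_mode: table-mean     # or `fixed` + fixed_threshold: 24.03
models:
  spline_k: 5
  max_lag: 4
  cv_folds: 10
  mrt_rule: min                # or 1se
  n_perm: 999
```

```sh
tropicatch simulate --config config.yaml --out inputs/   # write synthetic input CSVs
tropicatch all --config config.yaml                      # full pipeline
tropicatch mtc|trends|sensitivity|lags|composition|betadiv|tbi --config config.yaml
```

Outputs per region: series CSVs (`mtc.csv`, `warm_fraction_*.csv`,
anomalies), a trend table, the sensitivity table, lag-model tables,
regression-tree group memberships and CV table, ordination coordinates
and eigenvalues, SCBD/YCBD (with permutation p-values), and the
long-format TBI table with a gains-vs-losses test between the first and
last chronological groups.  A `manifest.json` records the config hash,
seed, and library versions; a rerun with the same config and seed is
bit-identical.

## Conventions worth knowing

- The warm/cold threshold is the arithmetic mean of the supplied
  preference table (ties count as cold); a fixed threshold can be
  configured instead.
- The regional split is half-open: latitude in [−60, 0) is inside the
  study box (the equator is out), and the 20° W meridian belongs to the
  eastern sector.
- The regression tree uses calendar year as its only predictor, so
  groups are contiguous blocks of years; cross-validation folds are
  contiguous blocks by default.
- Leave-one-out slope changes are signed,
  `100 · (slope_without − slope_full) / |slope_full|`, so sign flips
  exceed −100%.
- Lagged models use each lag's maximal overlap by default; set
  `models.lag_common_sample: true` to force a shared sample across lags.
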