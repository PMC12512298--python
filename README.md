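# anolechroma

Reusable analysis pipeline for physiological color change inferred from
segmented field photographs: dominant-color extraction and green/brown
classification, background-ring greenness comparison, hourly temperature
reconstruction from daily min/max, and season/temperature/background
statistical modeling with AIC selection — exercised end to end on synthetic
data with known ground truth.

## What it does

1. **`anolechroma.imagecolor`** — reduces each masked organism segment to
   the centroid of the largest of four k-means pixel clusters, labels it
   `green` (G > R + 2), `brown` (R > G + 5) or `unclear` (excluded from
   models, kept for audit), and computes the greenness index G/(R+G+B) for
   the segment and for a 20-pixel Chebyshev ring just outside the mask.
2. **`anolechroma.thermal`** — assigns observations to a 25-km
   equirectangular grid and reconstructs the temperature at the observation
   hour from the cell's daily min/max: sine daytime warming (peak at
   sunrise + (daylength + 4)/2) and logarithmic nighttime decay toward the
   next morning's minimum.
3. **`anolechroma.models`** — binomial models of green(1)/brown(0):
   penalized cyclic-cubic-spline GAMs of week-of-year and latitude
   (including a tensor-product interaction, smoothing by GCV), logistic
   regressions of hourly temperature with a breeding-season
   (1 April–30 September) interaction, OLS of organism greenness on
   background greenness with a temperature-confounder check, and AIC
   comparison (deviance + 2·edf) with logit-scale confidence bands
   back-transformed to probabilities.
4. **`anolechroma.synthdata`** — synthetic segment images, observation
   tables and daily temperatures with planted effects (temperature slope in
   the non-breeding season only, cyclic seasonal term whose amplitude
   changes with latitude), so every stage is testable against known truth.
5. **`anolechroma.pipeline`** — orchestration, retention accounting (every
   dropped record attributed to exactly one stage), and validation of a run
   against planted truth.

## CLI

All stages run from one YAML config and are composable; chaining the
subcommands reproduces `run-all` bit-exactly.

```sh
anole-chroma run-all --config config.yaml --out outdir --seed 1
anole-chroma simulate          --config config.yaml --out outdir
anole-chroma extract-colors    --config config.yaml --out outdir
anole-chroma attach-temperature --config config.yaml --out outdir
anole-chroma fit-models        --config config.yaml --out outdir
anole-chroma validate          --out outdir
```

A minimal config for a synthetic run:

```yaml
simulate: true
seed: 1
synthetic:
  n_records: 900
params:
  kmeans_k: 4
  ring_width: 20
```

For user data, replace `simulate` with input paths:

```yaml
inputs:
  images_dir: path/to/images   # <id>.png per record
  masks_dir: path/to/masks     # <id>.png, nonzero = organism
  records_csv: records.csv     # id, latitude, longitude, date, hour
  daily_temps_csv: daily.csv   # cell_col, cell_row, date, tmin, tmax
```

Outputs: `colors.csv` (per-segment dominant colors, labels, greenness),
`records_with_temp.csv`, `model_report.json` (coefficients, SEs, AIC
tables, deviance explained, per-season temperature slopes),
`seasonal_curves.csv` / `temperature_curves.csv` (prediction bands),
`retention.json` and `excluded.csv`.

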