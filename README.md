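# airequity

Tract-level analysis of the public-health co-benefits of decarbonization
scenarios: PM2.5 exposure aggregation, log-linear health impact assessment
with fixed/random-effects pooling of concentration-response coefficients,
value-of-statistical-life monetization with equal per-capita cost
allocation, and an environmental-justice assessment built on Lorenz curves
and the Suits Index. A synthetic-region generator stands in for
chemical-transport-model output and census data, so the whole pipeline runs
at desk scale with no downloads.

## What it computes

Given a tract table (population, baseline mortality incidence, 0–100
vulnerability score), gridded annual-mean PM2.5 fields (baseline plus
per-scenario reduction or concentration fields), a tract↔grid-cell weight
mapping, and per-scenario economy-wide costs, the pipeline produces:

- per-tract PM2.5 reductions and population-weighted summaries;
- per-tract avoided premature deaths
  (`incidence × population × (1 − exp(−β·ΔC))`), with β pooled across
  concentration-response functions by inverse-variance fixed effects,
  DerSimonian–Laird random effects, or an automatic Q-test rule;
- monetized benefits at a configurable VSL (default $9.7M, 2018$),
  per-capita allocated costs, cost per life saved, and net-benefit shares
  by population, tract, and disadvantaged-community (score ≥ 75) tract;
- statewide and per-county Suits Indices over the benefit distribution,
  Lorenz curve points, scenario equity deltas, and a dispersity measure
  (population SD of min–max-normalized tract benefits).

## CLI

```sh
# generate a synthetic study region (writes CSVs + a run-ready config.yaml)
airequity generate --spec spec.yaml --out region/

# run the full pipeline from a config
airequity run --config region/config.yaml --out results/

# one-shot demo: two-scenario synthetic region + full pipeline
airequity demo --seed 1 --out demo/

# per-county (Δ avoided deaths, Δ Suits) between two scenarios of a run
airequity compare --a broad --b targeted --run-dir demo/results
```

A region spec YAML takes `SyntheticRegionSpec` fields, e.g.

```yaml
n_tracts: 500
n_counties: 10
grid_rows: 35
grid_cols: 35
benefit_vulnerability_rho: 0.6
seed: 7
scenarios:
  broad:    {delta_mean: 0.68, rho: 0.4, cost: 1.06e+10}
  targeted: {delta_mean: 0.59, rho: 0.8, cost: 1.58e+10}
```

Pipeline outputs: per-scenario health-impact, valuation, county-equity and
Lorenz-curve CSVs (6 significant digits), an unrounded `summary.json`, and
a `manifest.json` recording the config hash, software version and every
default actually used. Reruns on the same inputs are byte-identical.

## Layout

```
src/airequity/
  synthetic.py   synthetic region generator (tunable vulnerability–benefit
                 rank correlation; Gaussian-smoothed random fields)
  exposure.py    grid→tract aggregation, deltas, population weighting
  health.py      health impact functions, CRF pooling
  valuation.py   monetization, cost allocation, net-benefit summary
  equity.py      Lorenz curves, Suits Index, county decomposition, dispersity
  fileio.py      CSV/NetCDF readers and writers
  pipeline.py    orchestration, demo, scenario comparison
  cli.py         click CLI (generate / run / demo / compare)
tests/           unit, property and acceptance suites
scripts/acceptance.py
```
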