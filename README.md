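# uhcd

A district-level universal health coverage (UHC) index pipeline: 24 tracer
indicators are pooled by geometric means through a three-level hierarchy
(indicators → tracer areas → tracer domains → index) on a 0–100 scale, with

- a **synthetic data generator** producing state-clustered district tables
  (normal state/district latent effects, domain-level targets, a poverty
  index negatively correlated with quality, wealth-graded subgroups,
  structured missingness),
- **imputation** via parent-district inheritance, stratified hot-deck, and
  OLS regression with state intercepts,
- an **equity** layer (subgroup indices via geometric-mean ratios,
  concentration index, achievement index),
- a **variance partition** of the index between and within states (in-house
  REML with a method-of-moments ANOVA cross-check), and
- a **sensitivity battery** (arithmetic / flat-geometric / inequality-adjusted
  variants and leave-one-out indicator drops, compared by Spearman ρ).

## CLI

```bash
uhcd run --config config.yaml --seed 11 --out out/   # full pipeline
uhcd simulate --seed 3 --out sim/                    # district + subgroup CSVs
uhcd impute --in sim/districts.csv --method all --seed 3 --out imputed.csv
uhcd index --in imputed.csv --method geometric --floor 0.1 --out results.csv
uhcd equity --districts imputed.csv --subgroups sim/subgroups.csv \
    --results results.csv --out eq/
uhcd decompose --results results.csv --districts imputed.csv --out dec/
uhcd sensitivity --districts imputed.csv --subgroups sim/subgroups.csv \
    --out sensitivity.csv
```

A minimal pipeline config:

```yaml
seed: 11
simulate:
  n_states: 33            # 687 districts by default
  missing: {pattern: by_domain, rate: 0.05}
index: {method: geometric, floor: 0.1}
threshold: 50.0
```

`uhcd run` writes, per stage: the simulated tables, the imputed table, the
per-district index results (overall index, service-coverage and
financial-risk-protection components, domain/area scores, tercile), a
summary-statistics table, a per-state table with tercile counts, the
variance decomposition and per-state coefficients of variation, equity
tables per inequality dimension, the sensitivity report, and a
machine-readable `run_log.json` (versions, seed, floor, imputation counts).
Runs are byte-identical given the same config and seed.

The indicator registry (hierarchy, orientations, 14-indicator equity
subset) is configuration: see `src/uhcd/data/registry.yaml` and pass an
alternative via `--registry` / the `registry` config key.

## Layout

| module | contents |
| --- | --- |
| `uhcd.model` | domain types, indicator registry, CSV readers/writers |
| `uhcd.simulate` | synthetic district/subgroup generator, missingness injection |
| `uhcd.impute` | inheritance, hot-deck, regression imputation |
| `uhcd.index` | orientation, geometric mean, hierarchical index, terciles, summaries |
| `uhcd.equity` | subgroup indices, fractional ranks, concentration/achievement indices |
| `uhcd.variance` | REML + method-of-moments variance components, state CVs, poverty correlation |
| `uhcd.sensitivity` | variant indices, leave-one-out drops, Spearman comparisons |
| `uhcd.cli` | pipeline orchestration and the `uhcd` command |
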