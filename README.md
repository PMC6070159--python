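# aqhealth

Health-impact assessment and economic valuation of air pollution from
multi-model ensembles of gridded concentration fields.

Regional chemistry–transport models disagree substantially about surface
concentrations of the health-relevant pollutants (O₃, CO, SO₂, PM₂.₅), and
that disagreement propagates directly into estimates of premature deaths and
their external costs. `aqhealth` implements the full impact-pathway chain
needed to study this: it evaluates each model against station observations,
combines the models into ensemble products (including an error-minimizing
member subset), converts concentrations into exposure metrics, applies a
linear exposure–response catalog against a gridded population, monetizes
the responses in EUR, and differences base-case against
emission-perturbation scenarios into avoided deaths and avoided costs. A
synthetic-data module generates study-shaped inputs — truth fields with
seasonal and diurnal structure, biased/noisy pseudo-models, sparse station
networks, population grids with age shares — so the entire chain is testable
without any model output downloads.

It is aimed at researchers in air-quality health impact assessment who want
a transparent, reproducible, seed-deterministic implementation of this
pipeline at desk scale.

## The model

Every health outcome follows the linear exposure–response form

```
R = α · δc · P
```

where `α` is the outcome-specific coefficient (e.g. 1.138·10⁻³ YOLL per
µg/m³ per person aged 30+ for chronic PM₂.₅ mortality), `δc` the
concentration metric above a counterfactual of zero, and `P` the exposed
population (cell count × age-group share × prevalence). CO, SO₂ and PM₂.₅
use the annual mean; O₃ uses SOMO35, the annual sum of daily-maximum
8-hour running-mean exceedances above 35 ppb (70 µg/m³). Chronic mortality
in years of life lost (YOLL) is converted to premature deaths with a
lifetable factor of 10.6; acute O₃/SO₂ deaths are added on top, and infant
mortality is reported separately:

```
PD = YOLL / 10.6 + acute deaths
```

Monetization uses value-of-life-year and value-of-statistical-life unit
values in 2013 EUR (57 510 per YOLL; 1 532 099 per acute death), with costs
attributed to pollutants by component-wise shares.

Ensemble products: the equal-weight multi-model mean, the per-cell median,
and the *optimal* ensemble — the member subset whose mean minimizes the
mean squared error against all valid station-hour observations, found by
exhaustive search over all 2^N − 1 subsets and then applied domain-wide.

Skill scores are Pearson r, normalized mean bias `NMB = Σ(M−O)/ΣO`,
normalized mean gross error `NMGE = Σ|M−O|/ΣO` and RMSE, computed on
hourly pairs filtered by observation availability or on monthly means.

## Worked example

The numbered scripts under `analysis/` run the demo study (a 12×12-cell
0.25° domain, one simulated year, five pseudo-models with known biases,
20 stations) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_evaluate_models.py
python analysis/03_build_ensembles.py
python analysis/04_assess_health_costs.py
python analysis/05_scenario_deltas.py
```

`02_evaluate_models.py` recovers the biases that were built into the
pseudo-models (member M1 was generated with a 0.85 multiplicative bias,
M2 with 1.10):

```
hourly NMB by member (mean over pollutants):
M1   -0.152
M2    0.101
M3   -0.244
M4   -0.002
M5   -0.077
```

`03_build_ensembles.py` selects the error-minimizing subsets:

```
O3: optimal subset {M2,M5} cuts station MSE by 79.4 % vs the all-member mean
PM25: optimal subset {M1,M2,M5} cuts station MSE by 24.1 % vs the all-member mean
```

`04_assess_health_costs.py` then reports, per member and ensemble product,
total premature deaths split into chronic and acute parts and the external
cost, e.g.

```
M1: PD 18,476 (chronic 4,883 + acute 13,594), cost 24.10 bn EUR
MM_mean: PD 35,974 (chronic 5,319 + acute 30,655), cost 50.53 bn EUR
```

and `05_scenario_deltas.py` differences a 20 % uniform concentration
reduction against the base case: annual-mean-driven outcomes fall by
exactly 20 %, while SOMO35-driven ozone mortality falls much faster
(here −78 to −100 %) because of the 70 µg/m³ threshold:

```
GLO20 ensemble: dPD -35,317 +/- 28,655; dCost -53.19 +/- 43.77 bn EUR
```

The same chain is available as a CLI (`aqhealth run --seed 1 --out out/`,
with per-stage subcommands `simulate | metrics | evaluate | ensemble |
assess | value | scenario`); reruns under the same seed are bit-identical,
verified by SHA-256 checksums in the run manifest.

## Layout

```
src/aqhealth/      core types & I/O, synthetic data, exposure metrics,
                   model evaluation, ensemble builder, health impacts,
                   valuation, scenario differencing, pipeline, CLI
analysis/          numbered demo-study drivers (write results/)
tests/             pytest suite incl. property-based checks
scripts/           acceptance.py
docs/methods.md    model description, parameter defaults, limitations
```
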