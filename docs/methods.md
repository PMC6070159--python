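# Methods

## Scope and data model

`aqhealth` implements an impact-pathway valuation chain over hourly gridded
surface concentrations of O₃, CO, SO₂ and PM₂.₅ on a regular lat–lon grid
(0.25° by default, mirroring the common grid onto which multi-model air
quality ensembles are interpolated). The chain is: synthetic or external
concentration fields → station evaluation → ensemble combination →
exposure metrics → linear exposure–response catalog × gridded population →
premature deaths → EUR costs → scenario differencing.

Grid conventions: cells are addressed by 0-based `(row, col)`, latitude
ascending, cell centers at `min + (index + 0.5)·resolution`; the time axis
is hourly, UTC, half-open `[start, end)`. Points exactly on a shared cell
edge resolve to the lower-index cell, so station-to-cell matching is
deterministic.

Units: the canonical internal unit is µg/m³ for all pollutants, because all
exposure–response coefficients are expressed per µg/m³. Gaseous fields in
ppb are converted at ingest with molar factors at 20 °C/1013 hPa — O₃
× 2.00, SO₂ × 2.66, CO × 1.16 — which are configurable; the conversion is
purely multiplicative and exactly invertible. CO is carried in µg/m³ (not
mg/m³) so the heart-failure CO coefficient applies directly.

## Synthetic inputs

The generator module produces study-shaped inputs; every generator is a
pure function of its arguments and an explicit integer seed.

* **Population** — `n_hotspots` exponentially decaying urban centers
  (scale 1° by default) over a 5 % uniform rural background; cell counts
  are integers by largest-remainder rounding, so they conserve the total
  exactly. Age shares default to a European-like structure (1 % infants
  under 9 months, 15.5 % children under 15, 83.5 % adults, 62 % aged 30+,
  18 % aged 65+); the three disjoint groups must partition the population
  and the adult groups must nest.
* **Truth fields** — mean level + annual sinusoid + 24-h sinusoid + a
  south–north gradient + a population-coupled hotspot term + spatially and
  temporally smoothed Gaussian noise, clipped at zero. Seasonal phases peak
  mid-July for O₃ and mid-January for CO/SO₂/PM₂.₅; the O₃ diurnal cycle
  peaks at 14:00 UTC. Default mean levels (O₃ 60, CO 300, SO₂ 5, PM₂.₅ 12
  µg/m³) are European-scale annual magnitudes.
* **Pseudo-models** — `member = smooth(mult_bias·truth + add_bias) +
  noise`, clipped at zero. The default five-member demo spans
  multiplicative biases 0.70–1.10, echoing the tens-of-percent
  underestimation spread reported for real regional ensembles, which gives
  the evaluation stage known targets: with noiseless observations a member
  with multiplicative bias *b* yields NMB = *b* − 1 exactly.
* **Stations** — placed without replacement, population-weighted by
  default (monitoring networks are densest where people live) with a small
  floor so rural cells stay possible; observed value = truth at the
  station cell + Gaussian noise (truncated at zero); each hour is missing
  independently with the configured rate.
* **Scenarios** — emission perturbations are represented as direct
  multiplicative concentration scalings, optionally inside a region mask.
  This is a deliberate linear-atmosphere simplification: real
  concentration responses to emission changes are chemically non-linear
  (especially for O₃), and nothing in this package emulates that. Scenario
  results on synthetic data therefore demonstrate the accounting,
  not atmospheric chemistry.

## Exposure metrics

* **annual_mean** — per-cell arithmetic mean over all hours.
* **dm8h** — per calendar day (UTC), the maximum of the 24 running 8-hour
  means whose window *ends* in that day. A window is valid with ≥ 6 of 8
  hours present; a day is valid with ≥ 75 % of its available in-period
  windows valid. Windows reaching before the period start are skipped, so
  day 1 offers 17 windows (validity floor 13) instead of 24 (floor 18).
  These data-capture rules follow common European reporting practice and
  only bite for observation-derived series; model fields are complete.
* **somo35** — Σ over days of max(0, DM8H − threshold), default threshold
  70 µg/m³ (35 ppb at the default O₃ factor; the factor convention is not
  universal, so the threshold is configurable). Invalid days contribute
  zero. SOMO35 is monotone in every hourly value and sub-linear under
  scaling: somo35(k·field) ≤ k·somo35(field) for k ≤ 1, which is why
  ozone impacts respond super-linearly to uniform concentration
  reductions.

## Model evaluation

Model values are sampled at each station's nearest cell and hours with
missing observations are dropped from both series. Statistics — Pearson r,
NMB = Σ(M−O)/ΣO, NMGE = Σ|M−O|/ΣO, RMSE (and MSE = RMSE²) — can be
computed on the hourly pairs or on monthly means; months with fewer than
25 % of their hours valid are dropped (the floor is configurable — it is a
package choice, not an external standard). r on a constant series is
reported as NaN (undefined), never 0, to avoid dragging summaries toward
zero skill. NMGE ≥ |NMB| always, with equality iff all residuals share one
sign.

## Ensemble products

The equal-weight mean and the per-cell median are the classic combinations.
The *optimal* ensemble is the non-empty member subset whose mean minimizes
the MSE against the pooled valid station-hour observations; the search is
exhaustive (2^N − 1 candidates, capped at N = 15, i.e. ≤ 32 767 subsets),
which is exact and cheap at study scale. Ties break toward the smaller
subset, then lexicographic member order, making selection deterministic.
One static subset is selected per pollutant over the whole period; the MSE
is evaluated on hourly pairs (not monthly means). The winning subset mean
is then extended to the full domain, so cells far from any station inherit
a selection made where observations exist — a documented approximation
that matters least exactly where the population (and hence the health
impact) is concentrated, since networks are densest there. By construction
the optimal subset's station MSE never exceeds the all-member mean's or
any single member's.

## Health impacts

Every outcome is `R = α · δc · P` summed over one or more components, with
a counterfactual concentration of 0 (configurable floor for sensitivity
runs), `δc` the metric value, and `P = counts × age share × prevalence`.
The shipped catalog has 16 outcomes: chronic bronchitis, restricted
activity days (a four-component composite whose negative terms deduct
hospital admissions to avoid double counting — negative cell values are
possible and reported as computed, with a warning), congestive heart
failure (PM₂.₅ + CO components), lung cancer, respiratory (PM₂.₅ + SO₂)
and cerebrovascular hospital admissions, three child-asthma and three
adult-asthma symptom outcomes (prevalences 7.6 % of under-15s and 5.9 % of
over-15s), acute SO₂ and O₃ mortality (SOMO35-driven, applied to the whole
population), chronic PM₂.₅ mortality in YOLL (adults 30+), and infant
mortality. Unit values are in 2013 EUR. The catalog round-trips through
YAML so alternative coefficient sets are plain config.

Age-group assignments the source table leaves open were fixed as package
defaults, all configurable: heart failure to the 65+ group; lung cancer to
30+; chronic bronchitis to 15+; acute mortality to the whole population;
infant mortality to the under-9-months group (an under/over-9-months
reading ambiguity exists; both are selectable). Child asthma uses the
under-15 population group even though its prevalence is quoted for
under-16s; the one-year mismatch is accepted. The asthma/bronchitis
baseline incidence rates are already folded into the printed α values and
are not represented separately.

Derived mortality scalars: `chronic_deaths = YOLL / lifetable_factor`
(default 10.6 years per death), `PD = chronic_deaths + acute_deaths`;
infant deaths are always a separate line and never enter PD (the published
ensemble arithmetic confirms this convention: 4111/10.6 + 26 ≈ 414
thousand). The whole stage is strictly linear in the metrics and additive
over spatial partitions, which the tests exploit.

## Valuation and summaries

`cost = response × unit value` per outcome. Pollutant attribution splits
multi-component outcomes by component response shares, so the four
pollutant columns sum to the total exactly (up to floating tolerance).
Ensemble summaries append column-wise Mean and Median rows over members,
unrounded; a separate reporting helper emulates published-table rounding
(CO to the nearest million EUR; other columns to the nearest 1000 million,
preserving exact half-thousands as produced by even-count medians). The
rounding emulation is inferred from the published tables, used only for
reporting, and never feeds back into any computation.

## Scenario differencing

Deltas are `perturbed − base` per outcome, for premature deaths and for
total cost (negative = avoided), with the same catalog, population and
lifetable factor enforced on both sides. Percent changes per cell come
from `100·(scen−base)/base` with zero-base cells flagged missing;
aggregated percent changes are population-weighted (ratio of summed deltas
to summed base responses). Multi-member summaries report the mean and
sample standard deviation (ddof = 1; undefined for a single member). For a
uniform scaling k with an annual-mean-only catalog, ΔPD/PD = k − 1
exactly; SOMO35-driven outcomes change by at least that much in magnitude.

## Pipeline, determinism and problem sizes

The pipeline derives one sub-seed per stage from the run seed (all below
2³¹), records every parameter, seed and output checksum in a JSON
manifest, and reproduces outputs bit for bit on rerun. The demo
configuration — a few-degree domain at 0.25° (12×12 to 20×20 cells), one
simulated year of hours, five members, 20 stations — was chosen so the
full chain completes in seconds to minutes on one CPU; the test suite uses
still smaller domains (days to two months). Nothing in the implementation
is specific to these sizes: the selection cap (N = 15) and vectorized
metrics accommodate full-study scale (hundreds of cells per side, ~13
members).

## Numerical choices

* Metric and combination operations are vectorized NumPy; DM8H uses
  cumulative sums for the running windows (NaN-aware counts for
  observation series).
* Subset-selection ties use strict `<` on float MSE, so exact ties keep
  the first candidate in (size, lexicographic) order.
* Largest-remainder rounding makes population totals exact; the
  one-hotspot zero-decay limit degenerates cleanly to a single cell.
* Station placement uses `Generator.choice` without replacement over cell
  weights; noise truncation at zero can bias very-low-mean series, so
  demo noise levels are small relative to mean levels.
* NetCDF I/O goes through xarray (CF-style attributes); the CSV fallback
  preserves metadata in header comments. Timestamps are parsed as UTC and
  held timezone-naive internally.

## Limitations

* No chemistry, meteorology, emissions or regridding: scenarios are
  concentration scalings (linear atmosphere), and synthetic members live
  on the common grid by construction.
* The exposure–response functions are linear with a zero counterfactual;
  no threshold or supra-linear low-concentration behavior, and no chronic
  O₃ mortality.
* Acute O₃ mortality applies its coefficient to raw SOMO35 (µg/m³·days)
  per person. Under the default synthetic ozone climate this makes the
  acute O₃ share of demo premature deaths far larger than the share
  reported for real continental assessments; the demo output illustrates
  the accounting chain, not a calibrated mortality split.
* The optimal-ensemble selection inherits any bias common to all members
  (e.g. shared emissions in real ensembles); nothing here removes
  offsetting biases.
* Passing tests on synthetic data demonstrate correctness of the
  arithmetic and the stated statistical recoveries, not fidelity to real
  monitoring networks, population rasters or model error structures.
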