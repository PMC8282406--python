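# Methods

This note documents the modelling conventions, parameter defaults, and
design choices of the `iemv` package, and what its synthetic test conditions
do and do not establish about behaviour on real data.

## Pipeline overview

Inputs are three long-format tables: a cause-sex-age-country-year mortality
surface on a fixed abridged age grid (twenty 5-year groups, terminal open
interval 95+), a country-year GNI per capita series (constant 2015 USD), and
country-sex-age population counts for 2020/2025/2030. The fitted pipeline:

1. **Panel validation.** Countries missing any of the three inputs (no
   mortality grid, no GNI anchor at 2017 or fewer than two observations for
   growth fitting, no population projections) are excluded and reported.
2. **Income classification.** 2016 GNI per capita against the 2016 World
   Bank bands (LIC ≤ $1005, LMIC $1006–3995, UMIC $3996–12,235). Countries
   above the UMIC ceiling are retained as the reference pool for UMIC
   trajectory targets but are not themselves valued.
3. **Trajectories.** Per cell, the high/low-performance 2030 targets are the
   10th/90th percentiles (linear interpolation between order statistics,
   the "type 7" estimator) of the next higher income group's pooled 2030
   base-case rates, one per reference country. Paths interpolate log-linearly
   from the 2016 observed rate; endpoints are set exactly rather than through
   the exp/log round-trip. Rates of exactly zero are floored at 1e-10
   (configurable) before the log transform — far below any plausible
   mortality rate, so the floor only prevents log(0).
4. **Demography.** Total mortality is the sum of the eight cause rates, with
   one cause at a time on its counterfactual path. Rate→probability uses
   q = 1 − exp(−5m) for closed intervals under the default constant-hazard
   convention; the classic midpoint actuarial form q = 5m/(1 + 2.5m) is a
   config switch (`prob_convention="midpoint"`). The terminal group has
   q = 1 and person-years l/m (so a zero terminal rate with survivors is an
   error; floor it). Life tables use radix 100,000 per sex; closed-interval
   person-years follow the convention matching the q formula (L = d/m under
   constant hazard, L = 5(l − d) + 2.5d under midpoint).
5. **SMU deltas.** Δ = (q_base − q_scenario) × 10⁴, the risk difference in
   standardized mortality units, per age group. The delta is the plain
   within-interval conditional probability difference; it is *not* weighted
   by cumulative survivorship from birth (an l(a)/l(0) weighting would mix
   the cohort perspective into a period quantity; the per-age-group SMU is
   the unit the valuation literature prices).
6. **Valuation.** VSL_{c,y} = VSL_base (I_{c,y}/I_base)^ε with the income
   ratio capped at `ratio_ceiling` (default 1.0 — no country valued above
   the US base) or fixed at 1/`fixed_ratio`. GNI is projected from each
   country's 2017 anchor at its group's mean endpoint log-growth rate
   r = ln(I_2017/I_2010)/7 (shorter windows ending 2017 are used when the
   series is shorter, with a warning). VSMU(35–39) = VSL × 10⁻⁴; other ages
   scale by e(a)/e(35) from the base-case life table of that country-sex-year.
7. **IEMV and aggregation.** IEMV = Δ_SMU × VSMU, 2015 USD per person at
   risk, undiscounted. Group summaries are population-weighted means over
   countries (weights: the sex-age stratum population), restricted to
   2020/2025/2030 where age-specific projections exist; population-scaled
   totals are available behind `scale="total"`.

## Parameter defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `vsl_base` | 9,400,000 | 2015 USD | standard US base VSL for benefit transfer |
| `i_base` | 57,900 | 2015 USD/capita | US GNI per capita matching the base VSL |
| `epsilon` | 1.0 | – | conventional cross-country income elasticity; the shipped sensitivity scenarios use 1.5 and fixed ratios 160/100 |
| `ratio_ceiling` | 1.0 | – | no country valued above the US base |
| `smu_size` | 1e-4 | risk | definition of the SMU (fixed) |
| `reference_age_start` | 35 | years | reference age group [35, 40) for VSMU age scaling (fixed) |
| zero floor | 1e-10 | deaths/person-year | log-transform guard, below any observable rate |
| growth window | 2010–2017 | years | last observed GNI span used for growth fitting |

## Uncertainty ranges

The 95% UR of an aggregated stratum is the weighted empirical 2.5th/97.5th
percentile of the *country-level* values, using plotting-position
interpolation ((cum_i − w_i/2)/W), with an unweighted switch. This is a
dispersion-across-countries statement, not a sampling-uncertainty statement:
with point forecasts as inputs there is no draw-level uncertainty to
propagate. A single-country group therefore has a degenerate UR at its own
value. This definition is a design choice of this package, documented here
precisely because other definitions (bootstrap over countries, forecast-draw
propagation) are defensible and would give different ranges.

## Synthetic study conditions

The generator (`synth_world`) emulates the three inputs with planted ground
truth. Defaults: 10 countries per analysis income group plus 4 high-income
reference countries; years 2010–2030; per-cause mortality
log m = level + slope·(age − 37.5)/10 + trend·(year − 2016) + country effect
(sd 0.15) + cell noise (sd 0.02, log scale); GNI anchored noise-free inside
each group's 2016 classification band (so classification is exact by
construction) growing at planted group rates 0.015–0.030/yr with the same
log noise off-anchor; populations with a smooth declining age structure.
Gompertz-like age slopes are positive for the NCD causes (cardiovascular
steepest, doubling roughly every 8 years of age) and negative for the
communicable and maternal/neonatal/nutritional block, giving life
expectancies at birth around 56 (LIC) to 67 (UMIC) years — deliberately in
the realistic range so the age-scaling mechanics operate on plausible e
schedules. One PRNG stream per table, all spawned from a single seed, so
regenerating one table never perturbs another and identical configs are
byte-identical. The small documentation fixture (3 countries per group,
seed 17) is regenerated on demand by `bundled_fixture()` rather than stored,
so examples can never drift from the generator.

What the synthetic conditions do **not** emulate: GBD's covariate-driven
forecasting model, epidemiological correlations between causes, migration or
cohort effects in population, GNI business cycles, and the real dispersion
of country mortality within an income group. Passing tests therefore
establish the *contracts* of the method — interpolation identities, life-table
correctness against an independent cohort-simulation oracle, scaling laws,
sign and ordering guarantees, exclusion logic, determinism — not the
magnitudes that real GBD/WDI/WPP inputs would produce. Published aggregate
dollar values are not reproducible without those inputs and are out of scope
here.

## Numerical choices

- Trajectory and quantile arithmetic is IEEE double throughout; endpoint
  identities (anchor, target, year-2016/2030 path values) are assigned, not
  recomputed through exp∘log, so they hold bitwise.
- The life-table oracle in the test suite integrates survival under the same
  piecewise-constant hazard on a daily grid by the trapezoidal rule,
  extending past age 95 until the survival mass is below 1e-18; agreement is
  required within 0.1% relative at every age on 200 random schedules.
- Quantile estimator everywhere: linear interpolation between order
  statistics (numpy default). The weighted quantile for URs degenerates to
  the plain value for a single country and is invariant to weight rescaling.
- Ties and degenerate inputs: equal reference rates give equal high/low
  targets (paths coincide, deltas are exactly 0, IEMV exactly 0); the
  midpoint q convention can reach q = 1 before the terminal group at extreme
  rates, after which l = 0 and e is reported as 0 for the empty cohort.
- Aggregation stores full-precision values; rounding is presentation-only.

## Known limitations

- Cause independence: altering one cause leaves the other seven untouched;
  no interaction dynamics (competing-risk feedback is one obvious extension).
- The high/low-performance scenarios are near-best/worst cases by
  construction (10th/90th percentile targets) and should be read as bounds.
- Benefit transfer from a US base VSL is an assumption, not an estimate of
  local willingness to pay; the sensitivity scenarios exist to bound it.
- Period life tables only; no cohort tables, no uncertainty propagation from
  forecast draws.
- UMIC targets require high-income reference countries in the panel (or an
  explicit `reference_surface`); the package refuses to extrapolate a
  reference distribution from fewer than two countries.
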