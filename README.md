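# iemv — income-equivalent monetary valuation of cause-specific mortality risk change

`iemv` prices deviations of cause-specific mortality from its forecast path
in low- and middle-income countries. It is aimed at health economists and
priority-setting analysts who want to compare, in a common monetary unit, the
stakes of accelerating (or failing to sustain) mortality decline across
disease categories, age groups, sexes, and country income groups.

## The model

For each country *c*, sex *s*, five-year age group *a* (20 groups, terminal
open interval 95+), and each of eight cause-of-death categories *d*
(neoplasms; cardiovascular; chronic respiratory; diabetes/blood/urogenital/
endocrine; mental; injuries; communicable; maternal/neonatal/nutritional),
three annual mortality-rate trajectories are defined over 2017–2030:

- **base-case** — the input forecast, unchanged;
- **high-performance** — converging by 2030 to the 10th percentile of the
  2030 base-case rate distribution of countries in the next higher income
  group (the best-performing tail);
- **low-performance** — converging to the 90th percentile of that
  distribution.

Counterfactual paths interpolate linearly in log rate between the observed
2016 rate and the 2030 target (a geometric progression). Causes are treated
as additive and independent: when cause *d* is on a counterfactual path the
other seven stay on the base-case, and the total rate m is their sum. Total
rates become conditional death probabilities q = 1 − exp(−5m) (constant
hazard within the interval; terminal q = 1), and the risk change is expressed
in standardized mortality units (SMU), 1 SMU = 10⁻⁴ change in q:

    Δ_SMU = (q_base − q_scenario) × 10⁴

Each SMU is valued by a country-year VSMU derived from a transferred value of
a statistical life,

    VSL_{c,y} = VSL_base × (I_{c,y} / I_base)^ε,
    VSMU_{c,y}(35) = VSL_{c,y} × 10⁻⁴,
    VSMU_{c,y}(a)  = (e_{a,s,y,c} / e_{35,s,y,c}) × VSMU_{c,y}(35),

with VSL_base = $9.4M, I_base = $57,900 (both 2015 USD), elasticity ε = 1 by
default, the income ratio capped at 1, and e the remaining life expectancy
from a base-case abridged life table — so younger deaths are valued more
wherever e declines with age. GNI per capita beyond its last observed year
(2017) grows at the country income group's mean exponential rate fitted on
2010–2017. The income-equivalent monetary value (IEMV) of a cell is
Δ_SMU × VSMU, in 2015 USD per person at risk, undiscounted: positive when
scenario risk is below the base-case, negative above it. Results aggregate
to income groups (2016 World Bank bands: LIC ≤ $1005; LMIC $1006–3995;
UMIC $3996–12,235) as population-weighted means with 95% uncertainty ranges
over countries, for 2020, 2025, and 2030. Three sensitivity scenarios vary
the VSL transfer (ε = 1.5; ε = 1 with the base-to-country income ratio fixed
at 160 or 100).

## Worked example

Real GBD Foresight / World Bank / UN WPP exports are not redistributable
here, so the package ships a deterministic synthetic-world generator with
planted ground truth. The bundled documentation fixture (3 countries per
income group plus 3 high-income reference countries, seed 17):

```python
import iemv

surface, gni, population, truth = iemv.bundled_fixture()
results = iemv.IemvModel(surface, gni, population).fit()
print(results.summary())
```

```
Income-Equivalent Monetary Valuation of Mortality Risk Change
==============================================================
Valuation years: 2017-2030   (anchor 2016, horizon 2030)
Rate->probability convention: constant_hazard
VSL transfer: base $9,400,000 at income $57,900, elasticity 1, ratio ceiling 1

income_group  n_countries  mean_growth_per_yr  mean_vsl_usd
         LIC            3              0.0241       156,265
        LMIC            3              0.0346       381,607
        UMIC            3              0.0254     1,740,298

High-income reference countries (not valued): 3
Excluded countries: none
```

The table shows, per income group, the number of valued countries, the mean
fitted GNI growth rate used for projection, and the mean transferred VSL over
2017–2030. One aggregated IEMV stratum — what a year on the low-performance
cardiovascular trajectory instead of the base-case costs a 70–74-year-old
woman's risk profile in LICs by 2030, per person at risk:

```python
agg = results.aggregate(2030)
row = agg[(agg.income_group == "LIC") & (agg.sex == "F") & (agg.age_start == 70)
          & (agg.cause == "cardiovascular") & (agg.scenario == "low")]
```

```
income_group sex  age_start          cause scenario       mean     ur_low     ur_high
         LIC   F         70 cardiovascular      low 861.008928 439.548901 1433.005994
```

The mean is positive here because the low-performance CVD target for these
synthetic LICs (the 90th percentile of the synthetic LMIC 2030 rates) still
sits *below* their own base-case forecast, so risk falls relative to the
base-case; the sign always tracks the direction of the risk change, cell by
cell.

The same pipeline runs from the shell:

```sh
iemv synth --seed 17 --n-per-group 10 --out panel/
iemv validate --mortality panel/mortality.csv --gni panel/gni.csv --population panel/population.csv
iemv run --mortality panel/mortality.csv --gni panel/gni.csv --population panel/population.csv --out out/
iemv aggregate --cells out/iemv.csv --population panel/population.csv \
    --income-groups out/income_groups.csv --out agg/
```

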