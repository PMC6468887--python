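# sugarsim

Health-impact simulation of the UK government's sugar reduction programme —
the voluntary agreement with industry to cut the sugar content of ten
high-sugar food categories (cereals, yogurts, biscuits, cakes, morning
goods, puddings, ice cream, chocolate and sweet confectionery, sweet
spreads) by 20% through **reformulation**, **portion size reduction**, and
**sales weighting** (shifting sales towards lower-sugar variants).

The package is for public-health modellers who want to run this class of
diet-policy scenario end to end on individual-level diet-diary data:

1. **Scenario engine** — applies each category's mechanisms to every food
   item (equal split of the 20% across a category's mechanisms; a
   natural-sugar allowance for dairy and dried fruit is removed before the
   cut and restored after) and aggregates per-person sugar and non-sugar
   calorie reductions.
2. **Imputation** — missing height, weight and physical activity are
   imputed by age-band × sex linear regressions chosen by likelihood-ratio
   tests, with stochastic residual noise.
3. **Weight change** — children: ΔW = 0.041 kg per gram of daily sugar
   removed (two-year effect), with kcal converted to grams at 3.75 kcal/g;
   adults: the Christiansen–Garby energy-balance equilibrium
   ΔW = ΔI / (PAL · (f·c_fat + (1−f)·c_lean)).
4. **Proportional multistate lifetable** — adult BMI reductions shift
   disease incidence through population impact fractions,
   PIF = (Σw·RR(b) − Σw·RR(b′)) / Σw·RR(b) with RR(b) = rr^(b−22),
   across 11 diseases (diabetes doubling as a risk factor for other
   diseases; lung and stomach cancer responding only through longevity),
   yielding cases averted, QALYs and healthcare costs over 10/30/100-year
   horizons with 2000-run Monte Carlo uncertainty intervals.

A synthetic-data module generates survey-like populations, diet diaries and
disease-parameter tables with the statistical structure the analysis
assumes, so the whole pipeline runs and is tested without any survey
download. See `docs/methods.md` for assumptions and defaults.

## Worked example

```python
import sugarsim as ss

bundle = ss.run_pipeline(ss.RunConfig(seed=1, n_people=1508, mc_runs=200))
print(bundle["table2"][["band", "sex", "sugar_kcal", "nonsugar_kcal",
                        "pct_of_baseline_sugar", "weight_change_kg",
                        "bmi_change"]].round(2))
```

```
 band    sex  sugar_kcal  nonsugar_kcal  pct_of_baseline_sugar  weight_change_kg  bmi_change
11-18 female       26.78           7.82                   6.94              0.29        0.14
11-18   male       26.61           7.27                   6.77              0.29        0.12
19-80 female       19.07           5.46                   4.96              1.76        0.67
19-80   male       22.79           6.61                   4.93              1.63        0.53
 4-10 female       20.77           6.12                   6.92              0.23        0.18
 4-10   male       19.51           5.34                   6.66              0.21        0.17
```

Each row is a survey-weighted age-band × sex summary: kcal/day removed from
sugar and (adults, via portion shrinkage) from non-sugar nutrients, the cut
as a percentage of baseline total sugar energy, and the resulting mean
weight (kg) and BMI reductions. Children lose ~0.2–0.3 kg over two years
from the sugar-only coefficient; adults reach a ~1.6–1.8 kg equilibrium
because non-sugar calories also count and the energy-balance model is
stronger per kcal.

```python
print(bundle["table3"].loc[["qalys_female", "cases_diabetes_female",
                            "cases_lung_cancer_male"]].round(0))
```

```
                         central      mean      lo95      hi95
output
qalys_female            140347.0  139864.0  107222.0  175969.0
cases_diabetes_female  -133677.0 -134688.0 -161344.0 -111926.0
cases_lung_cancer_male     339.0     335.0     249.0     432.0
```

Deltas are scenario − baseline over the 10-year horizon: QALYs gained,
diabetes cases averted (negative = fewer cases), and a small *increase* in
lung-cancer cases — a disease with no BMI link whose incidence rises only
because people live longer. Intervals are 2.5th–97.5th Monte Carlo
centiles. Because the bundled disease tables are synthetic, these absolute
magnitudes illustrate the mechanics, not a forecast for England.

The eight-column sensitivity grid (30-year and lifetime horizons, verified
anthropometrics only, including over-80s, 3-year-average BMI, and the
failure of each mechanism) is one call: `ss.run_sensitivity(config)`.

A CLI mirrors the library: `sugarsim synth | scenario | weights |
lifetable | run | sensitivity` (see `sugarsim --help`).

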