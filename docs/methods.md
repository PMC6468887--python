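# Methods

`sugarsim` simulates the health impact of the UK sugar reduction programme:
a voluntary agreement with industry to cut the sugar content of ten
high-sugar food categories by 20% through product reformulation, portion
size reduction, and a rebalancing of sales towards lower-sugar variants.
The package chains four models: a diet scenario engine, regression
imputation of anthropometrics, calorie-to-weight conversion, and a
proportional multistate lifetable with Monte Carlo uncertainty. This note
records the modelling assumptions, defaults, and design choices.

## Scenario engine

Each food item carries a category, grams consumed per day, grams of sugar
(of which a `natural_sugar` component may be exempt), and energy. The
default policy table assigns each of the ten targeted categories its
mechanisms; categories outside the table (`out_of_scope`) pass through
untouched.

Mechanics, per item with reduction fraction *r* (default 0.20) and sugar
energy density *d* (default 3.75 kcal/g, the carbohydrate-as-monosaccharide
convention):

* **Reformulation** and **sales weighting** remove their share of *r* from
  the item's allowance-adjusted sugar mass; energy falls by the removed
  grams × *d*. Sales weighting is mechanically identical to reformulation
  (an average sugar reduction across the category) and is tracked
  separately only for attribution and sensitivity toggling.
* **Portion reduction** scales amount, sugar, natural sugar, and energy by
  (1 − share), removing sugar and non-sugar calories proportionally.
  Uniform scaling of all nutrients — including the exempt natural sugar —
  is the physical interpretation of a smaller product.
* **Natural-sugar allowance**: for flagged categories (dairy: yogurts, ice
  cream; dried-fruit carriers: cakes, morning goods) the allowance is
  subtracted before the percentage cut and added back after, so only free
  sugars are reduced.

When a category has *k* mechanisms, each takes *r*/*k* of the reduction
(equal split), so the total in-scope sugar cut stays at *r*. When a
mechanism is disabled in a sensitivity run, its share is lost, not
redistributed — this represents the failure of that mechanism. Setting
`equal_split=False` instead redistributes the full reduction over the
enabled mechanisms.

Mechanism shares are applied additively against the baseline item, which
makes the decomposition exact: energy conservation
(`energy_after = energy_before − sugar_removed×d − nonsugar_removed`) and
per-mechanism additivity hold to machine precision, and the engine is
linear in item sugar content. No consumer substitution, compensatory
eating, or industry replacement of sugar with other calories is modelled.

## Imputation

Height, weight, and physical activity level (PAL) are imputed separately by
age band (4–18, 19–80) and sex. Candidate nested linear models
(intercept; + age; + age and daily kcal) are compared by likelihood-ratio
test at α = 0.05, searched forward with age before kcal (the search order
and α are configurable; both were open choices). Daily kcal is the
*baseline* diary energy — anthropometrics are baseline traits, so
imputation runs before the scenario arithmetic. Each missing value is the
linear prediction plus a Normal(0, residual SD) draw; draws at or below a
physical floor (0.6 m, 8 kg, PAL 1.05) are redrawn up to 10 times and then
truncated. Strata with fewer than 30 complete cases fall back to the
stratum mean and SD, recorded in the imputation report. Self-reported
values are kept but flagged so the "verified only" sensitivity can exclude
them. A single stochastic completion is drawn (no multiple imputation /
pooling rules).

## Weight and BMI

**Children (4–18).** Weight change is linear in sugar mass:
0.041 kg per gram of daily sugar, interpreted as the weight difference
accrued over two years; kcal/day deltas are converted to g/day at
3.75 kcal/g, giving a slope of 0.041/3.75 kg per kcal/day. Non-sugar
calories are deliberately excluded — the randomised evidence behind the
coefficient covers sugar only. Under this gram convention a
22.4 kcal/day reduction rounds to 0.24 kg; applying the coefficient
directly to kcal would give 0.92 kg per 22.4 kcal, which is not supported
by the underlying trials, so the gram interpretation is used throughout.

**Adults (19–80; 18-year-olds recomputed with this method before health
modelling).** The Christiansen–Garby energy-conservation equilibrium: a
sustained intake reduction ΔI (kcal/day) lowers weight until expenditure
matches, with expenditure per kg of tissue equal to the resting energy
cost of the lost tissue scaled by PAL:

    ΔW = ΔI / (PAL · (f·c_fat + (1−f)·c_lean))

Defaults: c_lean = 21.6 and c_fat = 4.5 kcal/kg/day (standard resting
tissue energy costs for this method), fat fraction of weight change
f = 0.60 (male) / 0.75 (female), PAL default 1.63 when missing. Both sugar
and non-sugar calories enter ΔI. The model is solved at the
infinite-horizon steady state rather than integrating a weight trajectory;
a dynamic (Hall-type) model is a named extension point only. At
(26.3 kcal/day, PAL 1.6, male defaults) the closed form gives ≈ 1.45 kg.

**BMI.** ΔBMI = ΔW / height². Children are classified against −2 SD / +1 SD
/ +2 SD growth-reference cut-offs (underweight below −2 SD; obese strictly
above +2 SD), 4-year-olds using the 5-year-old cut-offs; adults use
half-open bands at 18.5 / 25 / 30 / 35 (lower bound inclusive). The bundled
child cut-off table is a **synthetic** smooth approximation shipped so the
package runs self-contained; substantive use should load the real growth
reference via `BMIReference.from_csv` (schema: sex, age_years,
cut_minus2sd, cut_plus1sd, cut_plus2sd).

## Lifetable

Closed single-year cohorts of each sex (no new entrants) are followed for
10, 30, or 100 years with an annual time step and mid-year person-year
accrual. Each disease is a two-state healthy/diseased process with
age/sex-specific incidence and case fatality and no remission, under the
Markov assumption (rates do not depend on time since entry). Prevalence
follows dC/dt = i(1−C) − f·C, advanced by its exact constant-rate solution
over each interval; prevalence is not renormalised by differential
mortality — the proportional-lifetable simplification. Total mortality is
background mortality plus prevalence-weighted case fatality; survivors are
computed first and deaths as the exact difference, so cohort conservation
holds to the last bit.

The intervention enters through population impact fractions. Relative risk
is continuous in BMI, RR(b) = rr_per_unit^(b − 22) (reference BMI
configurable), and for each cohort

    PIF = (Σw·RR(b_baseline) − Σw·RR(b_scenario)) / Σw·RR(b_baseline)

over the survey individuals pooled into 5-year age bands (±1-year rolling
windows under the 3-year-average sensitivity). Scenario incidence is
baseline incidence × (1 − PIF), applied immediately (a lag hook exists,
default 0). Lung and stomach cancer carry unit RR and respond only through
longevity. Diabetes is both an endpoint and a risk factor: diseases with
`rr_diabetes` > 1 have scenario incidence scaled by
(1 + (rr−1)·C_diab,scenario) / (1 + (rr−1)·C_diab,baseline), i.e. the
adjustment is driven by the between-arm difference in diabetes prevalence.
Comorbidity combines multiplicatively: utility is the age norm times
Π(1 − u_d·C_d), costs are prevalence-weighted annual disease costs plus an
age/sex schedule of unrelated healthcare costs applied to all person-years
(so added life years carry the costs of diseases outside the model).
Both arms run through one code path; a null shift therefore produces
bitwise-zero deltas. QALYs and costs are undiscounted by default (no rate
is asserted by the source scenario; a fixed annual discount is available).

**Monte Carlo.** 2000 runs by default; per run, relative risks are drawn
lognormally on the log-RR scale, annual costs from a gamma with the
tabulated CV, and utility decrements from a moment-matched beta; PIFs are
recomputed from the drawn RRs each run. Zero-dispersion parameters stay
fixed. Point estimates report both the central (unperturbed) run and the
draw mean; intervals are empirical 2.5th–97.5th centiles. All randomness
descends from one master seed split into labelled substreams (synthesis,
imputation, Monte Carlo), so sensitivity runs share common random numbers.

## Synthetic data

The generator emulates diet-diary survey records: 1508 people aged 4–80 by
default, every single-year age covered, heights from age/sex growth curves,
BMI lognormal by age/sex calibrated so roughly a quarter of adults are
obese at baseline, PAL ≈ N(1.6, 0.15), survey weights lognormal with
CV 0.3, and missingness of 8% (height, weight) and 25% (PAL) with ~15%
self-reported anthropometrics. Diaries put ~7% of children's and ~5% of
adults' energy into in-scope sugars spread over 3–7 items from the ten
categories (sugar is 50–83% of each targeted item's energy), with a 10%
natural-sugar allowance in dairy/dried-fruit categories and an out-of-scope
filler item carrying the remaining energy plus the rest of a ~20% total
sugar share. Items are emitted directly as per-day averages (downstream
computation uses only daily means).

Under these defaults a 20% cut removes ≈5% of adults' and ≈7% of
children's baseline total sugar energy (≈1.0% and ≈1.4% of total energy),
adult weight change is ≈1.6–1.8 kg, and adult BMI falls ≈0.5–0.7 — the
realistic magnitudes for this intervention class. The generator does not
emulate diary-day sparsity: every synthetic person consumes some
portion-mechanism item, so the non-sugar calorie component has a positive
median, whereas real diaries are sparse enough that the median person has
none. Disease incidence/case-fatality curves, RRs per BMI unit, utility
decrements, and annual costs are plausible synthetic magnitudes, not any
published epidemiological inputs — absolute case counts, QALYs, and costs
from synthetic runs are therefore structural outputs, not forecasts for
England; passing tests demonstrate the mechanics and invariants of the
pipeline, not calibration to real surveillance data.

## Problem sizes and numerics

The shipped tests run the full pipeline at 1508 people with 2000 Monte
Carlo draws and a 10-year horizon (tens of seconds), with smaller
populations (150–300) for structural checks — sizes chosen to keep the
whole suite fast while still exercising the study-scale configuration.
Tolerances: the two-state closed form is matched to 1e-6 over 50 annual
steps; PIFs to 1e-12 against brute-force summation; the adult closed form
to 1e-9 kg against a bracketing root-finder; imputation recovery to 3 SE.
Degenerate inputs are handled explicitly: zero reduction is a strict no-op,
empty age bands are absent rather than zero, too-small imputation strata
fall back to means, and inconsistent nutrient data (energy less than sugar
energy) raise errors naming the offending category.

## Known limitations

* Absolute health outcomes are only as good as the disease tables supplied;
  the bundled tables are synthetic.
* The child weight model ignores non-sugar calories and assumes the sugary
  drinks evidence transfers to sugar in foods.
* The adult model is an equilibrium, not a trajectory; short-horizon
  results implicitly assume the new steady state is reached immediately.
* Prevalence dynamics ignore selection by differential mortality within
  the proportional assumption.
* No consumer or industry behavioural response is modelled; results
  describe the programme achieved in full.
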