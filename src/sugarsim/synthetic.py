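"""Synthetic diet-diary and disease-parameter generators.

Emulates the statistical structure of NDNS-style individual diet records
(per-person demographics, anthropometrics, physical activity; per-item food
category, amount, sugars, energy) so that the full scenario → weight →
lifetable pipeline can be exercised without any survey download. All
quantities are per-day averages over the diary period.

Nothing here reproduces real survey food codes or a real food composition
table; magnitudes are plausible for England but synthetic throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TABLE_CATEGORIES = [
    "breakfast_cereals",
    "yogurts",
    "biscuits",
    "cakes",
    "morning_goods",
    "puddings",
    "ice_cream",
    "chocolate_confectionery",
    "sweet_confectionery",
    "sweet_spreads_sauces",
]

#: categories whose sugar includes a naturally-occurring (dairy / dried
#: fruit) component exempt from the reduction target
NATURAL_SUGAR_CATEGORIES = frozenset({"yogurts", "ice_cream", "cakes", "morning_goods"})

DISEASES = [
    "cardiovascular_disease",
    "stroke",
    "diabetes",
    "breast_cancer",
    "colorectal_cancer",
    "lung_cancer",
    "stomach_cancer",
    "cirrhosis",
    "pancreatic_cancer",
    "kidney_cancer",
    "liver_cancer",
]

SUGAR_KCAL_PER_G = 3.75


@dataclass
class SyntheticConfig:
    """Configuration for the synthetic population and diary generator.

    Defaults mirror the modelled study conditions: 1508 respondents aged
    4-80, roughly 7% of children's energy and 5% of adults' energy coming
    from sugars in the targeted food categories, and realistic missingness
    in height, weight and physical activity level.
    """

    n_people: int = 1508
    seed: int = 1
    age_min: int = 4
    age_max: int = 80
    target_sugar_share_children: float = 0.07
    target_sugar_share_adults: float = 0.05
    #: share of total energy from *all* sugars (free + intrinsic, in and out
    #: of scope); the out-of-scope filler carries the remainder, so the
    #: programme's cut lands at a realistic fraction of baseline total sugar
    total_sugar_share: float = 0.20
    missingness_rates: dict = field(
        default_factory=lambda: {"height": 0.08, "weight": 0.08, "pal": 0.25}
    )
    self_reported_rate: float = 0.15
    category_mix: dict = field(
        default_factory=lambda: {c: 1.0 for c in TABLE_CATEGORIES}
    )
    natural_allowance_frac: float = 0.10
    survey_weight_cv: float = 0.3

    def validate(self) -> None:
        if self.n_people < 1:
            raise ValueError(f"n_people must be >= 1, got {self.n_people}")
        if not (0 <= self.age_min < self.age_max):
            raise ValueError(f"invalid age range [{self.age_min}, {self.age_max}]")
        for name in ("target_sugar_share_children", "target_sugar_share_adults",
                     "total_sugar_share", "self_reported_rate",
                     "natural_allowance_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for var, rate in self.missingness_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness_rates[{var}] must lie in [0, 1], got {rate}")
        unknown = set(self.category_mix) - set(TABLE_CATEGORIES)
        if unknown:
            raise ValueError(f"category_mix has unknown categories: {sorted(unknown)}")
        if sum(self.category_mix.values()) <= 0:
            raise ValueError("category_mix weights must sum to a positive total")


def _mean_height(age: np.ndarray, sex_male: np.ndarray) -> np.ndarray:
    """Smooth age/sex height curve (m): ~1.0 m at age 4 rising to adult stature."""
    adult = np.where(sex_male, 1.76, 1.63)
    child = 1.00 + (adult - 1.00) * np.clip((age - 4) / 14.0, 0, 1)
    return np.where(age >= 18, adult, child)


def _median_bmi(age: np.ndarray) -> np.ndarray:
    """Median BMI curve: ~15 at age 4 rising towards the adult distribution."""
    child = 15.0 + 6.5 * np.clip((age - 4) / 14.0, 0, 1) ** 1.2
    return np.where(age >= 19, 26.8, child)


def generate_population(config: SyntheticConfig) -> pd.DataFrame:
    """Generate a synthetic survey population.

    Returns one row per person: ``person_id, age, sex, height, weight,
    measurement_flag, pal, survey_weight``. Height/weight are drawn from
    age/sex-conditional lognormal BMI distributions calibrated so roughly a
    quarter of adults are obese or very obese at baseline; missingness is
    applied at the configured per-variable rates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_people
    ages_all = np.arange(config.age_min, config.age_max + 1)
    # guarantee coverage of every single-year age when n allows, then fill
    if n >= len(ages_all):
        extra = rng.choice(ages_all, size=n - len(ages_all), replace=True)
        age = np.concatenate([ages_all, extra])
    else:
        age = rng.choice(ages_all, size=n, replace=False)
    rng.shuffle(age)
    sex_male = rng.random(n) < 0.5
    sex = np.where(sex_male, "male", "female")

    height = _mean_height(age, sex_male) + rng.normal(0.0, 0.06, n) * np.clip(age / 18, 0.5, 1.0)
    bmi_sigma = np.where(age >= 19, 0.18, 0.13)
    bmi = np.exp(np.log(_median_bmi(age)) + rng.normal(0.0, 1.0, n) * bmi_sigma)
    weight = bmi * height**2

    pal = np.clip(rng.normal(1.6, 0.15, n), 1.2, None)
    survey_weight = _lognormal_weights(rng, n, config.survey_weight_cv)

    people = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "age": age.astype(int),
            "sex": sex,
            "height": height,
            "weight": weight,
            "pal": pal,
            "survey_weight": survey_weight,
        }
    )

    for var in ("height", "weight", "pal"):
        rate = config.missingness_rates.get(var, 0.0)
        if rate > 0:
            people.loc[rng.random(n) < rate, var] = np.nan

    missing_anthro = people["height"].isna() | people["weight"].isna()
    self_rep = (~missing_anthro) & (rng.random(n) < config.self_reported_rate)
    people["measurement_flag"] = np.select(
        [missing_anthro, self_rep], ["missing", "self_reported"], default="measured"
    )
    return people


def _lognormal_weights(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log(1 + cv**2))
    return rng.lognormal(-(sigma**2) / 2, sigma, n)


def _total_energy(age: np.ndarray, sex_male: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    adult = np.where(sex_male, 2300.0, 1900.0)
    child = 1300.0 + 60.0 * np.clip(age - 4, 0, 14)
    base = np.where(age >= 19, adult, child)
    return base * np.exp(rng.normal(0.0, 0.12, len(age)))


def generate_diaries(people: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Generate per-day-average food items for each person.

    The fraction of each person's total energy carried by in-scope (free)
    sugars in targeted categories is centred on the configured child/adult
    targets; sugar energy is split across a handful of in-scope items drawn
    from the category mix, and the remaining energy goes into a single
    out-of-scope filler item. Natural (exempt) sugar appears only in dairy
    and dried-fruit categories.
    """
    if len(people) == 0:
        raise ValueError("people must be non-empty")
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]).generate_state(1)[0])

    cats = [c for c in TABLE_CATEGORIES if config.category_mix.get(c, 0) > 0]
    probs = np.array([config.category_mix[c] for c in cats], dtype=float)
    probs /= probs.sum()

    rows: list[dict] = []
    ages = people["age"].to_numpy()
    sex_male = (people["sex"] == "male").to_numpy()
    energy_total = _total_energy(ages, sex_male, rng)
    targets = np.where(ages <= 18, config.target_sugar_share_children,
                       config.target_sugar_share_adults)

    for pid, age, etot, target in zip(people["person_id"], ages, energy_total, targets):
        sugar_kcal = target * etot * np.exp(rng.normal(0.0, 0.12))
        n_items = int(rng.integers(3, 8))
        shares = rng.dirichlet(np.ones(n_items) * 2.0)
        item_cats = rng.choice(cats, size=n_items, p=probs)
        for cat, share in zip(item_cats, shares):
            kcal = sugar_kcal * share
            sugar_g = kcal / SUGAR_KCAL_PER_G
            natural = (config.natural_allowance_frac * sugar_g
                       if cat in NATURAL_SUGAR_CATEGORIES else 0.0)
            # non-sugar energy in the same product (fat, starch, protein);
            # targeted products are sugar-dense, so sugar is most of the energy
            energy = kcal * rng.uniform(1.2, 2.0)
            amount = energy / rng.uniform(1.5, 4.5)
            rows.append(
                {"person_id": pid, "category": cat, "subgroup": f"{cat}_generic",
                 "amount": amount, "sugar": sugar_g, "natural_sugar": natural,
                 "energy": energy}
            )
        in_scope_energy = sum(r["energy"] for r in rows[-n_items:])
        filler = max(etot - in_scope_energy, 50.0)
        # remaining (intrinsic and untargeted free) sugars sit in the filler
        filler_sugar_kcal = min(max(config.total_sugar_share * etot - sugar_kcal, 0.0),
                                0.9 * filler)
        rows.append(
            {"person_id": pid, "category": "out_of_scope", "subgroup": "other_foods",
             "amount": filler / 1.8, "sugar": filler_sugar_kcal / SUGAR_KCAL_PER_G,
             "natural_sugar": 0.0, "energy": filler}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Disease, population and background tables (synthetic magnitudes)
# ---------------------------------------------------------------------------

# per disease: incidence at age 50 (/person-year), log-slope per year of age,
# case fatality (/person-year among prevalent), RR per BMI unit, RR conferred
# by prevalent diabetes, utility decrement while prevalent, annual cost (GBP)
_DISEASE_PARAMS = {
    "cardiovascular_disease": (0.0040, 0.07, 0.050, 1.06, 2.0, 0.10, 2500.0),
    "stroke":                 (0.0020, 0.08, 0.080, 1.04, 1.8, 0.15, 3000.0),
    "diabetes":               (0.0060, 0.04, 0.010, 1.18, 1.0, 0.05, 1500.0),
    "breast_cancer":          (0.0015, 0.03, 0.030, 1.03, 1.0, 0.12, 4000.0),
    "colorectal_cancer":      (0.0008, 0.07, 0.080, 1.04, 1.0, 0.12, 5000.0),
    "lung_cancer":            (0.0007, 0.07, 0.300, 1.00, 1.0, 0.20, 6000.0),
    "stomach_cancer":         (0.0002, 0.07, 0.250, 1.00, 1.0, 0.15, 5500.0),
    "cirrhosis":              (0.0004, 0.03, 0.100, 1.08, 1.0, 0.12, 3500.0),
    "pancreatic_cancer":      (0.0002, 0.08, 0.450, 1.03, 1.0, 0.20, 6500.0),
    "kidney_cancer":          (0.0003, 0.06, 0.100, 1.06, 1.0, 0.12, 5000.0),
    "liver_cancer":           (0.0002, 0.06, 0.350, 1.06, 1.0, 0.18, 6000.0),
}

AGE_TABLE_MAX = 110


def generate_disease_tables(seed: int = 1, age_max: int = AGE_TABLE_MAX) -> pd.DataFrame:
    """Synthetic long-format disease parameter table.

    One row per disease × sex × single-year age (18..age_max) with columns
    ``incidence, case_fatality, rr_per_bmi_unit, rr_diabetes,
    utility_decrement, annual_cost`` plus Monte Carlo dispersion columns
    (``rr_log_se, cost_cv, utility_se``). Breast cancer incidence is zero in
    males; lung and stomach cancer carry unit RR (they respond to the
    intervention only through longevity). Magnitudes are plausible but
    synthetic — they are not the epidemiological sources of any published
    model run.
    """
    rng = np.random.default_rng(seed)
    ages = np.arange(18, age_max + 1)
    frames = []
    for disease, (inc50, slope, cf, rr, rr_diab, util, cost) in _DISEASE_PARAMS.items():
        jitter = np.exp(rng.normal(0.0, 0.05, 3))
        inc_curve = np.minimum(inc50 * jitter[0] * np.exp(slope * (ages - 50)), 0.15)
        cf_curve = np.minimum(cf * jitter[1] * np.exp(0.02 * (ages - 50)), 0.6)
        for sex in ("male", "female"):
            inc_sex = inc_curve.copy()
            if disease == "breast_cancer" and sex == "male":
                inc_sex = np.zeros_like(inc_curve)
            frames.append(pd.DataFrame({
                "disease": disease, "sex": sex, "age": ages,
                "incidence": inc_sex, "case_fatality": cf_curve,
                "rr_per_bmi_unit": rr, "rr_diabetes": rr_diab,
                "utility_decrement": util,
                "annual_cost": cost * jitter[2],
                "rr_log_se": 0.015 if rr > 1.0 else 0.0,
                "cost_cv": 0.2,
                "utility_se": 0.02,
            }))
    return pd.concat(frames, ignore_index=True)


def generate_population_table(age_min: int = 18, age_max: int = 90) -> pd.DataFrame:
    """Synthetic closed-cohort population counts by sex and single-year age,
    shaped like a national adult age pyramid (counts decline at older ages)."""
    ages = np.arange(age_min, age_max + 1)
    counts = 340_000.0 * np.exp(-np.clip(ages - 55, 0, None) ** 2 / (2 * 22.0**2))
    frames = [pd.DataFrame({"sex": s, "age": ages, "count": counts})
              for s in ("male", "female")]
    return pd.concat(frames, ignore_index=True)


def generate_background_tables(age_max: int = AGE_TABLE_MAX) -> pd.DataFrame:
    """Background (all-other-cause) mortality, baseline utility, and
    unrelated annual healthcare cost per person-year, by sex and age.

    Mortality follows a Gompertz curve; utility declines linearly with age
    as in population EQ-5D norms; unrelated costs rise with age so that
    added life years carry realistic healthcare costs.
    """
    ages = np.arange(18, age_max + 1)
    frames = []
    for sex, scale in (("male", 1.1), ("female", 0.9)):
        mort = np.minimum(scale * 0.0008 * np.exp(0.095 * (ages - 40)), 0.7)
        utility = np.clip(0.94 - 0.0034 * (ages - 18), 0.3, 1.0)
        unrelated = 800.0 + 60.0 * np.clip(ages - 18, 0, None)
        frames.append(pd.DataFrame({
            "sex": sex, "age": ages, "background_mortality": mort,
            "baseline_utility": utility, "unrelated_cost": unrelated,
        }))
    return pd.concat(frames, ignore_index=True)


def write_synthetic_dataset(out_dir, config: SyntheticConfig | None = None) -> dict:
    """Write persons, food items, disease, population and background CSVs."""
    from pathlib import Path

    config = config or SyntheticConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    people = generate_population(config)
    items = generate_diaries(people, config)
    diseases = generate_disease_tables(config.seed)
    popn = generate_population_table()
    background = generate_background_tables()
    paths = {}
    for name, df in [("persons", people), ("food_items", items),
                     ("disease_params", diseases), ("population", popn),
                     ("background", background)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
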