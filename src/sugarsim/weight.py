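"""Calorie-to-weight conversion and BMI classification.

Children (4-18): weight change is linear in the sugar mass removed — the
trial-derived coefficient of 0.041 kg per gram of daily sugar over two
years; non-sugar calories are deliberately excluded, as no randomised
evidence links them to child weight.

Adults (19-80, with 18-year-olds recomputed by this method before health
modelling): an energy-conservation equilibrium. A sustained intake
reduction ΔI (kcal/day) lowers weight until expenditure has fallen by the
same amount; expenditure per kg of tissue is the resting energy cost of fat
and lean tissue scaled by the physical activity level (PAL), so

    ΔW = ΔI / (PAL · (f·c_fat + (1−f)·c_lean))

where f is the fat fraction of weight change (sex-specific, female > male).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

ADULT_THRESHOLDS = (18.5, 25.0, 30.0, 35.0)
ADULT_CATEGORIES = ("underweight", "normal", "overweight", "obese", "very_obese")
CHILD_CATEGORIES = ("underweight", "normal", "overweight", "obese")


@dataclass(frozen=True)
class ChildWeightParams:
    kg_per_g_sugar_per_day: float = 0.041  # 2-year weight difference per g/day
    sugar_energy_density: float = 3.75     # kcal per g of sugar

    def __post_init__(self):
        if self.kg_per_g_sugar_per_day <= 0 or self.sugar_energy_density <= 0:
            raise ValueError("child weight parameters must be positive")


@dataclass(frozen=True)
class AdultWeightParams:
    """Energy-balance coefficients: resting energy cost of lean and fat
    tissue (kcal/day per kg) and the sex-specific fat fraction of weight
    change. Defaults are the standard tissue-cost values for this method."""

    rmr_coeff_lean: float = 21.6
    rmr_coeff_fat: float = 4.5
    fat_fraction_of_change: dict = field(
        default_factory=lambda: {"male": 0.60, "female": 0.75})
    pal_default: float = 1.63

    def __post_init__(self):
        if self.rmr_coeff_lean <= 0 or self.rmr_coeff_fat <= 0:
            raise ValueError("tissue energy coefficients must be positive")
        for sex, f in self.fat_fraction_of_change.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fat fraction for {sex} must lie in [0, 1]")


def child_weight_change(sugar_kcal_delta, params: ChildWeightParams | None = None):
    """Two-year weight reduction (kg) from a daily sugar-energy reduction.

    Converts kcal/day to grams of sugar per day at the configured energy
    density and applies the linear coefficient. Accepts scalars or arrays.
    """
    params = params or ChildWeightParams()
    delta = np.asarray(sugar_kcal_delta, dtype=float)
    out = delta / params.sugar_energy_density * params.kg_per_g_sugar_per_day
    return float(out) if np.isscalar(sugar_kcal_delta) else out


def adult_weight_change(total_kcal_delta, sex, pal=None,
                        params: AdultWeightParams | None = None):
    """Equilibrium weight reduction (kg) for a sustained intake reduction.

    Includes both sugar and non-sugar calories. ``pal`` defaults to
    ``params.pal_default`` where missing; a nonpositive PAL is an error.
    Vectorised over numpy arrays / pandas Series.
    """
    params = params or AdultWeightParams()
    delta = np.asarray(total_kcal_delta, dtype=float)
    scalar = delta.ndim == 0
    pal_arr = np.asarray(
        params.pal_default if pal is None else pal, dtype=float)
    pal_arr = np.where(np.isnan(pal_arr), params.pal_default, pal_arr)
    if np.any(pal_arr <= 0):
        raise ValueError("physical activity level must be positive")
    f = np.vectorize(params.fat_fraction_of_change.__getitem__, otypes=[float])(
        np.asarray(sex))
    denom = pal_arr * (f * params.rmr_coeff_fat + (1.0 - f) * params.rmr_coeff_lean)
    out = delta / denom
    return float(out) if scalar else out


def bmi_change(weight_delta, height):
    """BMI reduction for a weight reduction: ΔBMI = Δw / height² (height m)."""
    h = np.asarray(height, dtype=float)
    if np.any(np.isnan(h)) or np.any(h <= 0):
        raise ValueError("height missing or nonpositive after imputation")
    out = np.asarray(weight_delta, dtype=float) / h**2
    return float(out) if np.isscalar(weight_delta) else out


class BMIReference:
    """Child BMI category cut-offs by sex and age (z-score based cut-offs at
    −2 SD, +1 SD and +2 SD of a growth-reference median), plus fixed adult
    thresholds.

    The bundled default table is a *synthetic* smooth approximation to a
    growth reference, shipped so the pipeline runs self-contained; replace
    it with the real reference cut-offs via ``BMIReference.from_csv`` for
    substantive use. Four-year-olds use the five-year-old cut-offs.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"sex", "age_years", "cut_minus2sd", "cut_plus1sd", "cut_plus2sd"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"BMI reference missing columns: {sorted(missing)}")
        cuts = table[["cut_minus2sd", "cut_plus1sd", "cut_plus2sd"]].to_numpy()
        if not (np.diff(cuts, axis=1) > 0).all():
            raise ValueError("BMI cut-offs must be strictly increasing within each row")
        self.table = table.set_index(["sex", "age_years"]).sort_index()

    @classmethod
    def from_csv(cls, path_or_buf) -> "BMIReference":
        return cls(pd.read_csv(path_or_buf))

    @classmethod
    def default(cls) -> "BMIReference":
        with resources.files("sugarsim.data").joinpath(
                "bmi_reference_synthetic.csv").open() as fh:
            return cls.from_csv(fh)

    def cutoffs(self, sex: str, age: int) -> tuple[float, float, float]:
        age = max(int(age), 5)  # 4-year-olds take the 5-year-old cut-offs
        try:
            row = self.table.loc[(sex, age)]
        except KeyError:
            raise ValueError(f"no BMI reference for sex={sex!r}, age={age}") from None
        return (float(row["cut_minus2sd"]), float(row["cut_plus1sd"]),
                float(row["cut_plus2sd"]))


def classify_bmi(age: int, sex: str, bmi: float,
                 reference: BMIReference | None = None) -> str:
    """BMI category for one person.

    Children (4-18): underweight below −2 SD, obese strictly above +2 SD,
    overweight strictly above +1 SD. Adults (19+): half-open bands at
    18.5 / 25 / 30 / 35 (lower bound inclusive).
    """
    if age < 4:
        raise ValueError(f"age {age} outside the modelled range (4+)")
    if age <= 18:
        reference = reference or BMIReference.default()
        m2, p1, p2 = reference.cutoffs(sex, age)
        if bmi < m2:
            return "underweight"
        if bmi <= p1:
            return "normal"
        if bmi <= p2:
            return "overweight"
        return "obese"
    idx = int(np.searchsorted(ADULT_THRESHOLDS, bmi, side="right"))
    return ADULT_CATEGORIES[idx]


def classify_bmi_series(people: pd.DataFrame, bmi,
                        reference: BMIReference | None = None) -> pd.Series:
    reference = reference or BMIReference.default()
    bmi = np.asarray(bmi, dtype=float)
    return pd.Series(
        [classify_bmi(a, s, b, reference)
         for a, s, b in zip(people["age"], people["sex"], bmi)],
        index=people.index, name="bmi_category")


def prevalence_table(people: pd.DataFrame, bmi_before, bmi_after,
                     reference: BMIReference | None = None) -> pd.DataFrame:
    """Survey-weighted BMI category prevalences before and after the
    intervention, by age band × sex, with the obese-class shrinkage
    expressed both as % of baseline obese cases and in percentage points.
    Obese counts pool the adult obese and very-obese classes.
    """
    from .scenario import age_band

    reference = reference or BMIReference.default()
    cat_before = classify_bmi_series(people, bmi_before, reference)
    cat_after = classify_bmi_series(people, bmi_after, reference)
    frame = people.assign(band=age_band(people["age"]),
                          cat_before=cat_before, cat_after=cat_after)
    rows = []
    for (band, sex), g in frame.groupby(["band", "sex"], sort=True):
        if band == "out_of_range":
            continue
        w = g["survey_weight"].to_numpy()
        total = w.sum()
        row = {"band": band, "sex": sex, "n": len(g)}
        for cat in ADULT_CATEGORIES:
            row[f"{cat}_before"] = 100 * w[(g["cat_before"] == cat)].sum() / total
            row[f"{cat}_after"] = 100 * w[(g["cat_after"] == cat)].sum() / total
        obese = ("obese", "very_obese")
        ob_before = w[g["cat_before"].isin(obese)].sum() / total
        ob_after = w[g["cat_after"].isin(obese)].sum() / total
        row["obese_shrinkage_pct"] = (
            100 * (ob_before - ob_after) / ob_before if ob_before > 0 else 0.0)
        row["obese_shrinkage_pp"] = 100 * (ob_before - ob_after)
        rows.append(row)
    return pd.DataFrame(rows)
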