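"""End-to-end pipeline: diaries → imputation → scenario → weight/BMI →
lifetable, plus the sensitivity grid.

The execution order is: impute baseline anthropometrics first (they are
baseline traits), then apply the sugar-reduction scenario, convert calorie
deltas to weight and BMI change (children by the linear sugar coefficient,
adults by the energy-balance equilibrium, 18-year-olds recomputed with the
adult method before health modelling), and finally run the proportional
multistate lifetable for adults with Monte Carlo uncertainty.

All randomness flows from one master seed split into labelled substreams
(synthesis, imputation, Monte Carlo), so paired sensitivity runs share
common random numbers with the main analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .impute import AnthropometricImputer
from .lifetable import (BMIShift, DiseaseTable, LifetableConfig,
                        MonteCarloConfig, flatten_delta, monte_carlo,
                        run_model)
from .scenario import (MECHANISMS, ScenarioParams, age_band, cohort_summary,
                       load_default_policy, load_policy, person_calorie_delta)
from .weight import (AdultWeightParams, BMIReference, ChildWeightParams,
                     adult_weight_change, bmi_change, child_weight_change,
                     prevalence_table)

SENSITIVITY_COLUMNS = (
    "30_year", "lifetime", "verified_only", "include_over_80s",
    "bmi_3yr_average", "excl_reformulation", "excl_portion",
    "excl_sales_weighting",
)


@dataclass
class RunConfig:
    """One pipeline run: scenario, imputation, weight and lifetable
    parameters plus the sensitivity switches."""

    seed: int = 1
    n_people: int = 1508
    reduction_fraction: float = 0.20
    sugar_energy_density: float = 3.75
    child_coefficient: float = 0.041
    horizon_years: int = 10
    mc_runs: int = 2000
    run_monte_carlo: bool = True
    exclude_mechanism: str | None = None
    verified_only: bool = False
    include_over_80s: bool = False
    bmi_rolling_3yr: bool = False
    imputation_alpha: float = 0.05
    discount_rate: float = 0.0

    def validate(self) -> None:
        if self.exclude_mechanism is not None and self.exclude_mechanism not in MECHANISMS:
            raise ValueError(f"exclude_mechanism must be one of {MECHANISMS} or None")
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if not 0 <= self.reduction_fraction <= 1:
            raise ValueError("reduction_fraction must lie in [0, 1]")

    def scenario_params(self) -> ScenarioParams:
        enabled = frozenset(m for m in MECHANISMS if m != self.exclude_mechanism)
        return ScenarioParams(
            reduction_fraction=self.reduction_fraction,
            sugar_energy_density=self.sugar_energy_density,
            mechanisms_enabled=enabled)


_PEOPLE_COLS = {"person_id", "age", "sex", "height", "weight",
                "measurement_flag", "pal", "survey_weight"}
_ITEM_COLS = {"person_id", "category", "amount", "sugar", "natural_sugar", "energy"}


def validate_schemas(people: pd.DataFrame, items: pd.DataFrame) -> None:
    for name, frame, cols in (("persons", people, _PEOPLE_COLS),
                              ("food_items", items, _ITEM_COLS)):
        missing = cols - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    if (items["amount"] <= 0).any():
        raise ValueError("food_items: amount must be positive")
    if (people["survey_weight"] < 0).any() or people["survey_weight"].sum() <= 0:
        raise ValueError("persons: survey weights must be non-negative with positive total")


def _load_inputs(config: RunConfig, data_dir):
    seeds = _substreams(config.seed)
    if data_dir is not None:
        d = Path(data_dir)
        people = pd.read_csv(d / "persons.csv")
        items = pd.read_csv(d / "food_items.csv")
        diseases = pd.read_csv(d / "disease_params.csv")
        population = pd.read_csv(d / "population.csv")
        background = pd.read_csv(d / "background.csv")
    else:
        synth_cfg = synthetic.SyntheticConfig(
            n_people=config.n_people, seed=int(seeds["synth"]),
            age_max=85 if config.include_over_80s else 80)
        people = synthetic.generate_population(synth_cfg)
        items = synthetic.generate_diaries(people, synth_cfg)
        diseases = synthetic.generate_disease_tables(int(seeds["synth"]))
        population = synthetic.generate_population_table()
        background = synthetic.generate_background_tables()
    return people, items, diseases, population, background, seeds


def _substreams(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    names = ("synth", "impute", "mc")
    return dict(zip(names, rng.integers(0, 2**31 - 1, size=len(names))))


def run_pipeline(config: RunConfig | None = None, data_dir=None,
                 policy: pd.DataFrame | None = None,
                 reference: BMIReference | None = None) -> dict:
    """Execute the full pipeline and return the report bundle.

    The bundle maps: ``table2`` (calorie/weight/BMI summary by band × sex),
    ``prevalence`` (BMI category shifts), ``attribution`` (% of calorie
    reduction by mechanism), ``table3`` (disease/QALY/cost deltas, with
    uncertainty intervals when Monte Carlo is on), ``imputation_report``,
    ``people`` (the completed person table with deltas), and ``config``.
    """
    config = config or RunConfig()
    config.validate()
    policy = policy if policy is not None else load_default_policy()
    reference = reference or BMIReference.default()

    people, items, diseases, population, background, seeds = _load_inputs(config, data_dir)
    validate_schemas(people, items)
    if not config.include_over_80s:
        population = population[population["age"] <= 80]

    # imputation of baseline anthropometrics
    kcal = items.groupby("person_id")["energy"].sum().rename("daily_kcal")
    people = people.merge(kcal, left_on="person_id", right_index=True, how="left")
    imputer = AnthropometricImputer(alpha=config.imputation_alpha)
    people = imputer.fit_transform(people, seed=int(seeds["impute"]))

    # scenario application
    params = config.scenario_params()
    deltas = person_calorie_delta(items, policy, params)
    summary = cohort_summary(deltas, people)

    # calorie → weight → BMI
    merged = people.merge(deltas, on="person_id", validate="one_to_one")
    child_params = ChildWeightParams(
        kg_per_g_sugar_per_day=config.child_coefficient,
        sugar_energy_density=config.sugar_energy_density)
    adult_params = AdultWeightParams()
    is_child = merged["age"] <= 18
    w_child = child_weight_change(merged["sugar_kcal_delta"].to_numpy(), child_params)
    w_adult = adult_weight_change(
        merged["total_kcal_delta"].to_numpy(), merged["sex"].to_numpy(),
        merged["pal"].to_numpy(), adult_params)
    merged["weight_delta"] = np.where(is_child, w_child, w_adult)
    # health modelling uses the adult method from age 18 upward
    merged["weight_delta_health"] = np.where(merged["age"] >= 18, w_adult, np.nan)
    merged["bmi_baseline"] = merged["weight"] / merged["height"] ** 2
    merged["bmi_delta"] = bmi_change(merged["weight_delta"].to_numpy(),
                                     merged["height"].to_numpy())
    merged["band"] = age_band(merged["age"])

    table2 = _table2(summary, merged)
    prev = prevalence_table(merged, merged["bmi_baseline"],
                            merged["bmi_baseline"] - merged["bmi_delta"], reference)
    attribution = mechanism_attribution(deltas, people)

    # adult BMI shift for the lifetable
    adults = merged[merged["age"] >= 18].copy()
    if config.verified_only:
        flags = [c for c in ("height_imputed", "weight_imputed", "pal_imputed")
                 if c in adults.columns]
        keep = adults["measurement_flag"].eq("measured")
        for c in flags:
            keep &= ~adults[c]
        adults = adults[keep]
    adults["bmi_delta_health"] = bmi_change(
        adults["weight_delta_health"].to_numpy(), adults["height"].to_numpy())
    shift = BMIShift.from_frame(adults.assign(
        bmi_scenario=adults["bmi_baseline"] - adults["bmi_delta_health"]))

    table = DiseaseTable(diseases)
    lt_config = LifetableConfig(horizon_years=config.horizon_years,
                                discount_rate=config.discount_rate)
    run_fn = lambda tbl: flatten_delta(  # noqa: E731
        run_model(shift, tbl, background, population, lt_config,
                  rolling_pif=config.bmi_rolling_3yr)["delta"], tbl.diseases)
    if config.run_monte_carlo:
        mc = MonteCarloConfig(n_runs=config.mc_runs, seed=int(seeds["mc"]))
        table3 = monte_carlo(run_fn, table, mc)
    else:
        central = run_fn(table)
        table3 = pd.DataFrame({"central": pd.Series(central)})
        table3.index.name = "output"

    return {
        "config": asdict(config),
        "seeds": {k: int(v) for k, v in seeds.items()},
        "table2": table2,
        "prevalence": prev,
        "attribution": attribution,
        "table3": table3,
        "imputation_report": imputer.report_,
        "people": merged,
    }


def _table2(summary: pd.DataFrame, merged: pd.DataFrame) -> pd.DataFrame:
    """Calorie, weight and BMI change summary by age band × sex."""
    extra = []
    for (band, sex), g in merged.groupby(["band", "sex"], sort=True):
        if band == "out_of_range":
            continue
        w = g["survey_weight"].to_numpy()
        extra.append({
            "band": band, "sex": sex,
            "weight_change_kg": float(np.average(g["weight_delta"], weights=w)),
            "bmi_change": float(np.average(g["bmi_delta"], weights=w)),
        })
    return summary.merge(pd.DataFrame(extra), on=["band", "sex"], how="left")


def mechanism_attribution(deltas: pd.DataFrame, people: pd.DataFrame) -> pd.DataFrame:
    """Percentage of the calorie reduction attributed to each mechanism, by
    age band. For children the portion-mechanism share counts only sugar
    calories (the child weight model cannot use non-sugar calories); for
    adults it includes the non-sugar calories removed by portion reduction.
    Shares sum to 100% within each band with any reduction.
    """
    merged = deltas.merge(people[["person_id", "age", "survey_weight"]],
                          on="person_id", validate="one_to_one")
    merged["band"] = age_band(merged["age"])
    rows = []
    for band, g in merged.groupby("band", sort=True):
        if band == "out_of_range":
            continue
        w = g["survey_weight"].to_numpy()
        adult_band = band == "19-80"
        portion_col = "kcal_portion" if adult_band else "kcal_portion_sugar"
        kcal = {
            "reformulation": float(np.average(g["kcal_reformulation"], weights=w)),
            "portion": float(np.average(g[portion_col], weights=w)),
            "sales_weighting": float(np.average(g["kcal_sales_weighting"], weights=w)),
        }
        total = sum(kcal.values())
        row = {"band": band, "total_kcal": total}
        for m in MECHANISMS:
            row[f"kcal_{m}"] = kcal[m]
            row[f"pct_{m}"] = 100 * kcal[m] / total if total > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_sensitivity(base: RunConfig | None = None, data_dir=None) -> pd.DataFrame:
    """Run the eight-column sensitivity grid.

    Columns: 30-year and lifetime (100-year) horizons, verified height and
    weight only, including over-80s, 3-year rolling-average BMI, and the
    failure of each single mechanism. Each run is deterministic (no Monte
    Carlo) and shares the master seed with the main analysis. Returns one
    row per output measure, one column per analysis.
    """
    base = base or RunConfig()
    variants = {
        "30_year": replace(base, horizon_years=30),
        "lifetime": replace(base, horizon_years=100),
        "verified_only": replace(base, verified_only=True),
        "include_over_80s": replace(base, include_over_80s=True),
        "bmi_3yr_average": replace(base, bmi_rolling_3yr=True),
        "excl_reformulation": replace(base, exclude_mechanism="reformulation"),
        "excl_portion": replace(base, exclude_mechanism="portion"),
        "excl_sales_weighting": replace(base, exclude_mechanism="sales_weighting"),
    }
    cols = {}
    for name, cfg in variants.items():
        cfg = replace(cfg, run_monte_carlo=False)
        bundle = run_pipeline(cfg, data_dir=data_dir)
        cols[name] = bundle["table3"]["central"]
    out = pd.DataFrame(cols)
    out.index.name = "output"
    return out[list(SENSITIVITY_COLUMNS)]


def write_report_bundle(bundle: dict, out_dir) -> None:
    """Write the report bundle as tidy CSVs plus a JSON run summary."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("table2", "prevalence", "attribution", "imputation_report"):
        bundle[name].to_csv(out / f"{name}.csv", index=False)
    bundle["table3"].to_csv(out / "table3.csv")
    summary = {"config": bundle["config"], "seeds": bundle["seeds"]}
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2))
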