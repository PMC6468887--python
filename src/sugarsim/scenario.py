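"""Sugar reduction scenario engine.

Applies the programme's three mechanisms to individual food items:

* **reformulation** and **sales weighting** remove a share of the item's
  in-scope sugar mass, and with it the corresponding sugar energy;
* **portion reduction** shrinks the whole product, removing sugar and
  non-sugar calories proportionally.

Each food category is served by a fixed subset of mechanisms (the default
policy table). When several mechanisms act on a category they split the
total reduction equally, so the overall in-scope sugar cut stays at the
target fraction. Categories carrying naturally-occurring dairy/dried-fruit
sugar have that allowance removed before the percentage cut and added back
afterwards, so only free sugars are reduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

MECHANISMS = ("reformulation", "portion", "sales_weighting")
#: mechanisms that remove sugar mass only (no non-sugar calories)
SUGAR_ONLY_MECHANISMS = ("reformulation", "sales_weighting")

BANDS = [("4-10", 4, 10), ("11-18", 11, 18), ("19-80", 19, 200)]


@dataclass(frozen=True)
class ScenarioParams:
    """Programme parameters: the headline reduction fraction, the energy
    density of sugar, and which mechanisms are in force (for sensitivity
    runs simulating the failure of one mechanism)."""

    reduction_fraction: float = 0.20
    sugar_energy_density: float = 3.75
    mechanisms_enabled: frozenset = frozenset(MECHANISMS)
    equal_split: bool = True

    def __post_init__(self):
        if not 0.0 <= self.reduction_fraction <= 1.0:
            raise ValueError(
                f"reduction_fraction must lie in [0, 1], got {self.reduction_fraction}")
        if self.sugar_energy_density <= 0:
            raise ValueError("sugar_energy_density must be positive")
        unknown = set(self.mechanisms_enabled) - set(MECHANISMS)
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")


def load_default_policy() -> pd.DataFrame:
    """Default category → mechanism policy table (one row per category;
    0/1 columns for each mechanism and the natural-sugar allowance flag)."""
    with resources.files("sugarsim.data").joinpath("policy_table.csv").open() as fh:
        return load_policy(fh)


def load_policy(path_or_buf) -> pd.DataFrame:
    policy = pd.read_csv(path_or_buf)
    required = {"category", "natural_allowance", *MECHANISMS}
    missing = required - set(policy.columns)
    if missing:
        raise ValueError(f"policy table missing columns: {sorted(missing)}")
    in_scope = policy[list(MECHANISMS)].sum(axis=1)
    if (in_scope == 0).any():
        bad = policy.loc[in_scope == 0, "category"].tolist()
        raise ValueError(f"categories with no mechanism: {bad}")
    return policy.set_index("category", drop=False)


def _mechanism_shares(policy_row, params: ScenarioParams) -> dict[str, float]:
    """Per-mechanism share of the reduction fraction for one category.

    With ``equal_split`` the category's mechanisms split the target equally
    and a disabled mechanism's share is lost (not redistributed) — this is
    the mechanism-failure sensitivity. Without ``equal_split`` the enabled
    mechanisms split the full target between themselves.
    """
    listed = [m for m in MECHANISMS if policy_row[m]]
    active = [m for m in listed if m in params.mechanisms_enabled]
    shares = dict.fromkeys(MECHANISMS, 0.0)
    if not active:
        return shares
    denom = len(listed) if params.equal_split else len(active)
    for m in active:
        shares[m] = params.reduction_fraction / denom
    return shares


def apply_policy_to_item(item, policy: pd.DataFrame, params: ScenarioParams):
    """Apply the category's mechanisms to one food item.

    ``item`` is a mapping with keys ``category, amount, sugar,
    natural_sugar, energy``. Returns ``(adjusted_item: dict,
    by_mechanism: dict of kcal/day removed)``. Out-of-scope items are
    returned unchanged with zero attribution.
    """
    item = dict(item)
    if item["category"] == "out_of_scope":
        return item, dict.fromkeys(MECHANISMS, 0.0)
    if item["category"] not in policy.index:
        raise ValueError(f"unknown food category: {item['category']!r}")
    row = policy.loc[item["category"]]
    shares = _mechanism_shares(row, params)
    d = params.sugar_energy_density

    natural = item["natural_sugar"] if row["natural_allowance"] else 0.0
    s_eff = item["sugar"] - natural  # allowance-adjusted (free) sugar
    r_sugar = sum(shares[m] for m in SUGAR_ONLY_MECHANISMS)
    p = shares["portion"]

    new = dict(item)
    new["sugar"] = item["sugar"] - r_sugar * s_eff - p * item["sugar"]
    new["natural_sugar"] = item["natural_sugar"] * (1 - p)
    new["amount"] = item["amount"] * (1 - p)
    new["energy"] = item["energy"] - r_sugar * s_eff * d - p * item["energy"]
    if new["sugar"] < -1e-12 or new["energy"] < -1e-12:
        raise ValueError(
            f"inconsistent nutrient data for category {item['category']!r}: "
            f"adjusted sugar={new['sugar']:.3f} g, energy={new['energy']:.3f} kcal")

    by_mech = {
        "reformulation": shares["reformulation"] * s_eff * d,
        "sales_weighting": shares["sales_weighting"] * s_eff * d,
        "portion": p * item["energy"],
    }
    return new, by_mech


def apply_scenario(items: pd.DataFrame, policy: pd.DataFrame,
                   params: ScenarioParams) -> pd.DataFrame:
    """Vectorised application of :func:`apply_policy_to_item` to an item table.

    Returns a copy of ``items`` with adjusted ``amount/sugar/natural_sugar/
    energy`` plus per-item delta columns ``sugar_kcal_delta,
    nonsugar_kcal_delta, kcal_reformulation, kcal_portion,
    kcal_sales_weighting`` (all kcal/day removed, >= 0).
    """
    known = set(policy.index) | {"out_of_scope"}
    unknown = set(items["category"]) - known
    if unknown:
        raise ValueError(f"unknown food categories: {sorted(unknown)}")

    d = params.sugar_energy_density
    share_rows = {c: _mechanism_shares(policy.loc[c], params) for c in policy.index}
    share_rows["out_of_scope"] = dict.fromkeys(MECHANISMS, 0.0)
    allowance = {c: bool(policy.loc[c, "natural_allowance"]) for c in policy.index}
    allowance["out_of_scope"] = False

    cat = items["category"]
    r_sugar = cat.map(lambda c: sum(share_rows[c][m] for m in SUGAR_ONLY_MECHANISMS)).to_numpy()
    share_ref = cat.map(lambda c: share_rows[c]["reformulation"]).to_numpy()
    share_sw = cat.map(lambda c: share_rows[c]["sales_weighting"]).to_numpy()
    p = cat.map(lambda c: share_rows[c]["portion"]).to_numpy()
    has_allow = cat.map(allowance).to_numpy()

    sugar = items["sugar"].to_numpy(float)
    natural = np.where(has_allow, items["natural_sugar"].to_numpy(float), 0.0)
    energy = items["energy"].to_numpy(float)
    s_eff = sugar - natural

    out = items.copy()
    out["sugar"] = sugar - r_sugar * s_eff - p * sugar
    out["natural_sugar"] = items["natural_sugar"].to_numpy(float) * (1 - p)
    out["amount"] = items["amount"].to_numpy(float) * (1 - p)
    out["energy"] = energy - r_sugar * s_eff * d - p * energy
    if (out["sugar"] < -1e-12).any() or (out["energy"] < -1e-12).any():
        bad = out.loc[(out["sugar"] < -1e-12) | (out["energy"] < -1e-12), "category"].unique()
        raise ValueError(f"inconsistent nutrient data in categories: {list(bad)}")

    out["sugar_kcal_delta"] = (r_sugar * s_eff + p * sugar) * d
    out["nonsugar_kcal_delta"] = p * (energy - sugar * d)
    out["kcal_reformulation"] = share_ref * s_eff * d
    out["kcal_sales_weighting"] = share_sw * s_eff * d
    out["kcal_portion"] = p * energy
    # sugar-only share of the portion mechanism (used for child attribution,
    # where non-sugar calories cannot enter the weight model)
    out["kcal_portion_sugar"] = p * sugar * d
    return out


def person_calorie_delta(items: pd.DataFrame, policy: pd.DataFrame,
                         params: ScenarioParams) -> pd.DataFrame:
    """Per-person calorie deltas (kcal/day removed), decomposed into sugar
    and non-sugar parts and attributed to each mechanism, alongside the
    person's baseline sugar kcal and total energy."""
    adjusted = apply_scenario(items, policy, params)
    base = items.assign(
        baseline_sugar_kcal=items["sugar"] * params.sugar_energy_density,
        baseline_energy_kcal=items["energy"],
    )
    delta_cols = ["sugar_kcal_delta", "nonsugar_kcal_delta",
                  "kcal_reformulation", "kcal_portion", "kcal_portion_sugar",
                  "kcal_sales_weighting"]
    out = adjusted.groupby("person_id")[delta_cols].sum()
    out[["baseline_sugar_kcal", "baseline_energy_kcal"]] = (
        base.groupby("person_id")[["baseline_sugar_kcal", "baseline_energy_kcal"]].sum())
    out["total_kcal_delta"] = out["sugar_kcal_delta"] + out["nonsugar_kcal_delta"]
    return out.reset_index()


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, v))


def age_band(age) -> pd.Series | str:
    """Map age(s) to the reporting bands 4-10 / 11-18 / 19-80."""
    def one(a):
        for name, lo, hi in BANDS:
            if lo <= a <= hi:
                return name
        return "out_of_range"
    if np.isscalar(age):
        return one(age)
    return pd.Series([one(a) for a in age], index=getattr(age, "index", None))


def cohort_summary(deltas: pd.DataFrame, people: pd.DataFrame) -> pd.DataFrame:
    """Survey-weighted summary of calorie deltas by age band × sex.

    Reports weighted mean sugar and non-sugar kcal removed, those deltas as
    percentages of baseline sugar kcal and of baseline total energy, and the
    weighted median/IQR of the (highly skewed) non-sugar component. Bands
    with no people are absent from the output.
    """
    merged = deltas.merge(
        people[["person_id", "age", "sex", "survey_weight"]], on="person_id",
        validate="one_to_one")
    merged["band"] = age_band(merged["age"])
    rows = []
    for (band, sex), g in merged.groupby(["band", "sex"], sort=True):
        if band == "out_of_range" or len(g) == 0:
            continue
        w = g["survey_weight"].to_numpy()
        wmean = lambda col: float(np.average(g[col], weights=w))  # noqa: E731
        nonsugar = g["nonsugar_kcal_delta"].to_numpy()
        rows.append({
            "band": band, "sex": sex, "n": len(g),
            "sugar_kcal": wmean("sugar_kcal_delta"),
            "nonsugar_kcal": wmean("nonsugar_kcal_delta"),
            "total_kcal": wmean("total_kcal_delta"),
            "pct_of_baseline_sugar": 100 * wmean("sugar_kcal_delta") / wmean("baseline_sugar_kcal"),
            "pct_of_baseline_energy": 100 * wmean("sugar_kcal_delta") / wmean("baseline_energy_kcal"),
            "pct_total_of_baseline_energy": 100 * wmean("total_kcal_delta") / wmean("baseline_energy_kcal"),
            "nonsugar_median": _weighted_quantile(nonsugar, w, 0.5),
            "nonsugar_q1": _weighted_quantile(nonsugar, w, 0.25),
            "nonsugar_q3": _weighted_quantile(nonsugar, w, 0.75),
        })
    return pd.DataFrame(rows)
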