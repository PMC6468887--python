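"""Proportional multistate lifetable with BMI-mediated disease risk.

Closed single-year birth-cohorts of each sex are followed for a fixed
horizon. Each modelled disease is a two-state (healthy/diseased) process
with age-specific incidence and case fatality; disease prevalences evolve
independently and combine multiplicatively for comorbidity, mortality,
utility and cost (the proportional assumption). Diabetes additionally acts
as a risk factor: prevalent diabetes multiplies the incidence of affected
diseases, so the scenario arm feeds its diabetes prevalence back into other
disease rates relative to the baseline arm.

The intervention enters through population impact fractions (PIFs): the
shift in the weighted BMI distribution of each cohort scales disease
incidence by (1 − PIF). Both arms share one code path, so a null shift
yields bitwise-identical arms.

Monte Carlo uncertainty varies relative risks (lognormal), annual disease
costs (gamma) and utility decrements (beta) across runs; intervals are the
empirical 2.5th–97.5th centiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("male", "female")


# ---------------------------------------------------------------------------
# population impact fraction
# ---------------------------------------------------------------------------

def rr_from_bmi(bmi, rr_per_unit: float, reference_bmi: float = 22.0):
    """Continuous relative risk: RR(bmi) = rr_per_unit ** (bmi − reference)."""
    return np.power(rr_per_unit, np.asarray(bmi, dtype=float) - reference_bmi)


def pif(baseline_rr, scenario_rr, weights) -> float:
    """Population impact fraction from paired exposure distributions.

    PIF = (Σw·RR_baseline − Σw·RR_scenario) / Σw·RR_baseline. Zero when the
    distributions coincide; positive when exposure falls under an
    increasing risk function. The two RR vectors must describe the same
    people with the same weights.
    """
    b = np.asarray(baseline_rr, dtype=float)
    s = np.asarray(scenario_rr, dtype=float)
    w = np.asarray(weights, dtype=float)
    if b.shape != s.shape or b.shape != w.shape:
        raise ValueError(
            f"mismatched PIF inputs: baseline {b.shape}, scenario {s.shape}, "
            f"weights {w.shape}")
    if b.size == 0:
        raise ValueError("PIF requires a nonempty exposure distribution")
    denom = float(np.sum(w * b))
    return (denom - float(np.sum(w * s))) / denom


def pif_from_bmi(baseline_bmi, scenario_bmi, weights, rr_per_unit,
                 reference_bmi: float = 22.0) -> float:
    return pif(rr_from_bmi(baseline_bmi, rr_per_unit, reference_bmi),
               rr_from_bmi(scenario_bmi, rr_per_unit, reference_bmi), weights)


# ---------------------------------------------------------------------------
# disease parameter container
# ---------------------------------------------------------------------------

class DiseaseTable:
    """Disease parameters in array form, indexed disease × age per sex.

    Built from the long-format CSV schema ``disease, sex, age, incidence,
    case_fatality, rr_per_bmi_unit, rr_diabetes, utility_decrement,
    annual_cost`` (plus optional Monte Carlo dispersion columns
    ``rr_log_se, cost_cv, utility_se``). Ages outside the tabulated range
    are clamped to the nearest tabulated age.
    """

    RATE_COLS = ("incidence", "case_fatality")
    SCALAR_COLS = ("rr_per_bmi_unit", "rr_diabetes", "utility_decrement",
                   "annual_cost", "rr_log_se", "cost_cv", "utility_se")

    def __init__(self, df: pd.DataFrame):
        required = {"disease", "sex", "age", "incidence", "case_fatality",
                    "rr_per_bmi_unit", "utility_decrement", "annual_cost"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"disease table missing columns: {sorted(missing)}")
        df = df.copy()
        for col, default in (("rr_diabetes", 1.0), ("rr_log_se", 0.0),
                             ("cost_cv", 0.0), ("utility_se", 0.0)):
            if col not in df.columns:
                df[col] = default
        if (df[["incidence", "case_fatality"]] < 0).any().any():
            raise ValueError("disease rates must be non-negative")
        if (df["rr_per_bmi_unit"] <= 0).any():
            raise ValueError("relative risks must be positive")
        if not df["utility_decrement"].between(0, 1).all():
            raise ValueError("utility decrements must lie in [0, 1]")

        self.diseases = list(df["disease"].drop_duplicates())
        self.ages = np.sort(df["age"].unique())
        n_d, n_a = len(self.diseases), len(self.ages)
        self.incidence = {}
        self.case_fatality = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].set_index(["disease", "age"]).sort_index()
            inc = np.empty((n_d, n_a))
            cf = np.empty((n_d, n_a))
            for i, dis in enumerate(self.diseases):
                block = sub.loc[dis]
                inc[i] = block["incidence"].reindex(self.ages).to_numpy()
                cf[i] = block["case_fatality"].reindex(self.ages).to_numpy()
            if np.isnan(inc).any() or np.isnan(cf).any():
                raise ValueError(f"incomplete age coverage for sex={sex!r}")
            self.incidence[sex] = inc
            self.case_fatality[sex] = cf
        first = df.drop_duplicates("disease").set_index("disease")
        for col in self.SCALAR_COLS:
            setattr(self, col, first[col].reindex(self.diseases).to_numpy(float))

    def age_index(self, ages) -> np.ndarray:
        clamped = np.clip(ages, self.ages[0], self.ages[-1])
        return np.searchsorted(self.ages, clamped)

    def perturbed(self, rng: np.random.Generator,
                  vary=("relative_risks", "costs", "utilities")) -> "DiseaseTable":
        """A copy with one Monte Carlo parameter draw applied.

        Relative risks: lognormal on the log-RR scale; costs: gamma with
        the tabulated coefficient of variation; utility decrements: beta by
        moment matching. A zero dispersion is treated as a fixed parameter.
        """
        import copy

        out = copy.copy(self)
        if "relative_risks" in vary:
            se = self.rr_log_se
            log_rr = np.log(self.rr_per_bmi_unit)
            draw_log = np.where(se > 0, rng.normal(log_rr, se), log_rr)
            out.rr_per_bmi_unit = np.exp(draw_log)
        if "costs" in vary:
            cv = self.cost_cv
            cost = self.annual_cost
            shape = np.where(cv > 0, 1.0 / np.maximum(cv, 1e-12) ** 2, 1.0)
            scale = np.where((cv > 0) & (cost > 0), cost / shape, 0.0)
            drawn = np.where((cv > 0) & (cost > 0),
                             rng.gamma(shape, np.maximum(scale, 1e-300)), cost)
            out.annual_cost = drawn
        if "utilities" in vary:
            u, sd = self.utility_decrement, self.utility_se
            valid = (sd > 0) & (u > 0) & (u < 1) & (sd**2 < u * (1 - u))
            nu = u * (1 - u) / np.maximum(sd, 1e-12) ** 2 - 1.0
            a = np.maximum(u * nu, 1e-6)
            b = np.maximum((1 - u) * nu, 1e-6)
            drawn = np.where(valid, rng.beta(a, b), u)
            out.utility_decrement = drawn
        return out


# ---------------------------------------------------------------------------
# cohort state and single lifetable step
# ---------------------------------------------------------------------------

@dataclass
class CohortState:
    """State of the sex-specific cohort array at one point in model time."""

    sex: str
    start_ages: np.ndarray          # (n_cohorts,)
    alive: np.ndarray               # (n_cohorts,)
    prevalence: np.ndarray          # (n_cohorts, n_diseases)
    year: int = 0
    life_years: float = 0.0
    qalys: float = 0.0
    costs: float = 0.0
    deaths: float = 0.0
    cases: np.ndarray = None        # (n_diseases,) cumulative incident cases

    @property
    def current_ages(self) -> np.ndarray:
        return self.start_ages + self.year


def step_cohort(state: CohortState, table: DiseaseTable,
                background: pd.DataFrame, pifs: np.ndarray | None = None,
                diabetes_prev_ref: np.ndarray | None = None,
                baseline_utility=None,
                dt: float = 1.0, discount_rate: float = 0.0) -> CohortState:
    """Advance every cohort of one sex by ``dt`` years.

    Disease prevalence follows the two-state flow dC/dt = i(1−C) − f·C,
    stepped by its exact constant-rate solution over the interval. Total
    mortality is background mortality plus prevalence-weighted case
    fatality; survivors, deaths, person-years, incident cases, QALYs and
    costs are accrued with mid-interval person-year weighting.

    ``pifs`` (n_diseases, n_cohorts) scales incidence by (1 − PIF);
    ``diabetes_prev_ref`` is the reference arm's diabetes prevalence used
    for the diabetes-as-risk-factor adjustment (the arm's own prevalence is
    used as reference when absent, making the adjustment exactly one).
    """
    sex = state.sex
    ai = table.age_index(state.current_ages)
    inc = table.incidence[sex][:, ai]        # (n_d, n_c)
    cf = table.case_fatality[sex][:, ai]
    C = state.prevalence.T                   # (n_d, n_c)

    if np.any(C < -1e-12) or np.any(C > 1 + 1e-12):
        d_idx, c_idx = np.argwhere((C < -1e-12) | (C > 1 + 1e-12))[0]
        raise ValueError(
            f"prevalence outside [0,1] for disease {table.diseases[d_idx]!r}, "
            f"{sex} cohort starting at age {state.start_ages[c_idx]}")

    if pifs is not None:
        inc = inc * (1.0 - pifs)
    # diabetes as a risk factor: multiplicative incidence adjustment driven
    # by the difference in diabetes prevalence between arms
    rr_diab = np.asarray(table.rr_diabetes)
    if (rr_diab > 1).any():
        try:
            di = table.diseases.index("diabetes")
        except ValueError:
            di = None
        if di is not None:
            c_own = C[di]
            c_ref = c_own if diabetes_prev_ref is None else diabetes_prev_ref
            factor = ((1.0 + (rr_diab[:, None] - 1.0) * c_own[None, :])
                      / (1.0 + (rr_diab[:, None] - 1.0) * c_ref[None, :]))
            inc = inc * factor

    # exact two-state solution over the interval at constant rates
    tot = inc + cf
    with np.errstate(divide="ignore", invalid="ignore"):
        c_star = np.where(tot > 0, inc / np.where(tot > 0, tot, 1.0), 0.0)
    C_next = np.where(tot > 0, c_star + (C - c_star) * np.exp(-tot * dt), C)

    bg = _lookup(background, sex, state.current_ages, "background_mortality")
    m = bg + (cf * C).sum(axis=0)
    # survivors first, deaths as the exact difference, so
    # alive(t+1) + deaths == alive(t) without rounding slack
    alive_next = state.alive * np.exp(-m * dt)
    deaths = state.alive - alive_next
    py = 0.5 * (state.alive + alive_next) * dt
    C_mid = 0.5 * (C + C_next)

    disc = (1.0 + discount_rate) ** (-(state.year + 0.5 * dt))
    new_cases = (inc * (1.0 - C_mid) * py[None, :]).sum(axis=1) * dt

    bu = (_lookup(background, sex, state.current_ages, "baseline_utility")
          if baseline_utility is None else np.asarray(baseline_utility, float))
    utility = bu * np.prod(1.0 - table.utility_decrement[:, None] * C_mid, axis=0)
    qalys = float((py * utility).sum()) * disc

    disease_cost = (table.annual_cost[:, None] * C_mid * py[None, :]).sum()
    unrel = _lookup(background, sex, state.current_ages, "unrelated_cost")
    costs = float(disease_cost + (unrel * py).sum()) * disc

    return CohortState(
        sex=sex, start_ages=state.start_ages, alive=alive_next,
        prevalence=C_next.T, year=state.year + 1,
        life_years=state.life_years + float(py.sum()),
        qalys=state.qalys + qalys, costs=state.costs + costs,
        deaths=state.deaths + float(deaths.sum()),
        cases=(state.cases if state.cases is not None else 0.0) + new_cases,
    )


class _PreparedBackground:
    """Background schedules as clamped per-sex arrays for fast age lookup."""

    COLS = ("background_mortality", "baseline_utility", "unrelated_cost")

    def __init__(self, df: pd.DataFrame):
        self.arrays = {}
        for sex in SEXES:
            sub = df[df["sex"] == sex].sort_values("age")
            ages = sub["age"].to_numpy(int)
            self.age_min, self.age_max = int(ages[0]), int(ages[-1])
            self.arrays[sex] = {c: sub[c].to_numpy(float) for c in self.COLS}

    def lookup(self, sex: str, ages: np.ndarray, col: str) -> np.ndarray:
        idx = np.clip(ages, self.age_min, self.age_max) - self.age_min
        return self.arrays[sex][col][idx]


def _lookup(background, sex: str, ages: np.ndarray, col: str) -> np.ndarray:
    if not isinstance(background, _PreparedBackground):
        background = _PreparedBackground(background)
    return background.lookup(sex, ages, col)


# ---------------------------------------------------------------------------
# full model run
# ---------------------------------------------------------------------------

@dataclass
class LifetableConfig:
    horizon_years: int = 10
    reference_bmi: float = 22.0
    discount_rate: float = 0.0
    lag_years: int = 0
    pif_age_band_width: int = 5


@dataclass
class BMIShift:
    """Per-sex paired BMI distributions: the same individuals (with survey
    weights and baseline ages) before and after the intervention."""

    data: dict = field(default_factory=dict)  # sex -> (ages, bmi0, bmi1, w)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BMIShift":
        """Build from a DataFrame with columns sex, age, bmi_baseline,
        bmi_scenario, survey_weight."""
        out = cls()
        for sex, g in frame.groupby("sex"):
            out.data[sex] = (g["age"].to_numpy(int),
                             g["bmi_baseline"].to_numpy(float),
                             g["bmi_scenario"].to_numpy(float),
                             g["survey_weight"].to_numpy(float))
        return out

    def pif_table(self, table: DiseaseTable, start_ages: np.ndarray, sex: str,
                  reference_bmi: float = 22.0, band_width: int = 5,
                  rolling: bool = False) -> np.ndarray:
        """PIF per disease × cohort start age.

        Individuals are pooled into fixed age bands (default 5 years), or a
        ±1-year rolling window when ``rolling`` — the 3-year rolling-average
        smoothing used to stabilise small per-age samples. Cohorts older
        than the oldest sampled person reuse the last band.
        """
        ages, bmi0, bmi1, w = self.data[sex]
        n_d = len(table.diseases)
        out = np.zeros((n_d, len(start_ages)))
        # group cohort start ages that share a pooling window, so each PIF
        # is computed once per (window, disease)
        masks: dict[tuple, np.ndarray] = {}
        cohort_key = []
        for a in start_ages:
            if rolling:
                key = ("r", int(a))
                mask = np.abs(ages - a) <= 1
                if not mask.any():
                    mask = np.abs(ages - a) <= band_width
            else:
                lo = int(ages.min() + ((a - ages.min()) // band_width) * band_width)
                key = ("b", lo)
                mask = (ages >= lo) & (ages < lo + band_width)
            if not mask.any():
                key = ("last",)
                mask = ages >= ages.max() - band_width  # reuse oldest band
            masks.setdefault(key, mask)
            cohort_key.append(key)
        for key, mask in masks.items():
            cols = [ci for ci, k in enumerate(cohort_key) if k == key]
            x0, x1, wm = bmi0[mask] - reference_bmi, bmi1[mask] - reference_bmi, w[mask]
            for di in range(n_d):
                rr = table.rr_per_bmi_unit[di]
                if rr == 1.0:
                    continue  # longevity-only disease: PIF identically zero
                denom = float(np.sum(wm * rr**x0))
                out[di, cols] = (denom - float(np.sum(wm * rr**x1))) / denom
        return out


def _run_arm(table: DiseaseTable, background: pd.DataFrame,
             population: pd.DataFrame, config: LifetableConfig,
             pifs: dict | None, diabetes_ref: dict | None):
    """Run one arm of the lifetable for both sexes.

    Returns (results dict, diabetes prevalence trajectory dict). The same
    function serves baseline (pifs None) and scenario arms, so a null
    intervention reproduces the baseline bitwise.
    """
    if not isinstance(background, _PreparedBackground):
        background = _PreparedBackground(background)
    results = {}
    diab_traj = {}
    try:
        di = table.diseases.index("diabetes")
    except ValueError:
        di = None
    for sex in SEXES:
        sub = population[population["sex"] == sex].sort_values("age")
        start_ages = sub["age"].to_numpy(int)
        state = CohortState(
            sex=sex, start_ages=start_ages,
            alive=sub["count"].to_numpy(float),
            prevalence=np.zeros((len(start_ages), len(table.diseases))),
            cases=np.zeros(len(table.diseases)))
        traj = []
        initial_alive = state.alive.sum()
        for t in range(config.horizon_years):
            traj.append(state.prevalence[:, di].copy() if di is not None
                        else np.zeros(len(start_ages)))
            step_pifs = None
            if pifs is not None and t >= config.lag_years:
                step_pifs = pifs[sex]
            ref = diabetes_ref[sex][t] if diabetes_ref is not None else None
            state = step_cohort(
                state, table, background, pifs=step_pifs,
                diabetes_prev_ref=ref, discount_rate=config.discount_rate)
        results[sex] = {
            "cases": dict(zip(table.diseases, state.cases)),
            "life_years": state.life_years,
            "qalys": state.qalys,
            "costs": state.costs,
            "deaths": state.deaths,
            "initial_alive": float(initial_alive),
            "final_alive": float(state.alive.sum()),
        }
        diab_traj[sex] = traj
    return results, diab_traj


def run_model(bmi_shift: BMIShift, table: DiseaseTable,
              background: pd.DataFrame, population: pd.DataFrame,
              config: LifetableConfig | None = None,
              rolling_pif: bool = False) -> dict:
    """Run baseline and scenario arms and return their difference.

    Output: ``{"baseline": ..., "scenario": ..., "delta": ...}`` where each
    arm maps sex → cases per disease, life years, QALYs and costs, and
    ``delta`` is scenario − baseline (positive QALY delta = health gained;
    negative cost delta = net saving).
    """
    config = config or LifetableConfig()
    if config.horizon_years < 1:
        raise ValueError("horizon_years must be >= 1")
    if not isinstance(background, _PreparedBackground):
        background = _PreparedBackground(background)
    baseline, diab_traj = _run_arm(table, background, population, config,
                                   pifs=None, diabetes_ref=None)
    pifs = {}
    for sex in SEXES:
        start_ages = np.sort(population.loc[population["sex"] == sex, "age"].unique())
        pifs[sex] = bmi_shift.pif_table(
            table, start_ages, sex, config.reference_bmi,
            config.pif_age_band_width, rolling=rolling_pif)
    scenario, _ = _run_arm(table, background, population, config,
                           pifs=pifs, diabetes_ref=diab_traj)
    delta = {}
    for sex in SEXES:
        delta[sex] = {
            "cases": {d: scenario[sex]["cases"][d] - baseline[sex]["cases"][d]
                      for d in table.diseases},
            "life_years": scenario[sex]["life_years"] - baseline[sex]["life_years"],
            "qalys": scenario[sex]["qalys"] - baseline[sex]["qalys"],
            "costs": scenario[sex]["costs"] - baseline[sex]["costs"],
        }
    return {"baseline": baseline, "scenario": scenario, "delta": delta}


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloConfig:
    n_runs: int = 2000
    seed: int = 1
    vary: tuple = ("relative_risks", "costs", "utilities")

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


def flatten_delta(delta: dict, diseases) -> dict:
    """Flatten a per-sex delta dict to scalar outputs keyed
    ``<measure>_<sex>`` and ``cases_<disease>_<sex>``."""
    flat = {}
    for sex, d in delta.items():
        for measure in ("qalys", "costs", "life_years"):
            flat[f"{measure}_{sex}"] = d[measure]
        for dis in diseases:
            flat[f"cases_{dis}_{sex}"] = d["cases"][dis]
    return flat


def monte_carlo(run_fn, table: DiseaseTable,
                mc: MonteCarloConfig | None = None) -> pd.DataFrame:
    """Propagate parameter uncertainty through ``run_fn``.

    ``run_fn(table)`` must return a flat dict of scalars. Each run applies
    one parameter draw (:meth:`DiseaseTable.perturbed`) and re-runs the
    model. Returns a frame indexed by output key with the central
    (unperturbed) value, the Monte Carlo mean, and the 2.5th/97.5th centile
    uncertainty interval. Deterministic given the seed.
    """
    mc = mc or MonteCarloConfig()
    rng = np.random.default_rng(mc.seed)
    if not mc.vary:
        logger.info("no parameters vary: intervals will have zero width")
    central = run_fn(table)
    draws = []
    for _ in range(mc.n_runs):
        draws.append(run_fn(table.perturbed(rng, vary=mc.vary)))
    frame = pd.DataFrame(draws)
    out = pd.DataFrame({
        "central": pd.Series(central),
        "mean": frame.mean(),
        "lo95": frame.quantile(0.025),
        "hi95": frame.quantile(0.975),
    })
    out.index.name = "output"
    return out
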