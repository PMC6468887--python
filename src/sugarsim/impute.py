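"""Regression imputation of height, weight and physical activity level.

Missing anthropometrics are imputed separately by age band (children 4-18,
adults 19-80) and sex. Within each stratum, nested linear models
(intercept-only; + age; + age + daily kcal) are compared by likelihood-ratio
test and the largest model whose added term is significant is kept. Imputed
values are the linear prediction plus a Normal draw with the stratum
residual standard deviation, so imputation preserves the residual spread of
the observed data rather than shrinking it to the regression line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

VARIABLES = ("height", "weight", "pal")
#: nested predictor chain, searched in order
PREDICTOR_CHAIN = ((), ("age",), ("age", "daily_kcal"))

_FLOORS = {"height": 0.6, "weight": 8.0, "pal": 1.05}


@dataclass
class ImputationModel:
    """Fitted stratum model for one variable: predictors, OLS coefficients
    (intercept first), and residual standard deviation."""

    variable: str
    band: str
    sex: str
    predictors: tuple
    coefficients: np.ndarray
    residual_sd: float
    n_complete: int
    fallback: bool = False

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[p].to_numpy(float) for p in self.predictors])
        return X @ self.coefficients


def _impute_band(age) -> pd.Series:
    return pd.Series(np.where(np.asarray(age) <= 18, "4-18", "19-80"),
                     index=getattr(age, "index", None))


class AnthropometricImputer:
    """Stratified regression imputer with stochastic residual noise.

    Parameters
    ----------
    alpha : float
        Significance level of the likelihood-ratio tests in the forward
        model search (age is tested before daily kcal).
    min_stratum : int
        Minimum complete cases per stratum for a regression fit; smaller
        strata fall back to the stratum mean and SD (recorded in the report).
    max_redraws : int
        Attempts to redraw an imputed value that falls at or below the
        physical floor for its variable before truncating at the floor.

    Attributes (set by :meth:`fit`)
    -------------------------------
    models_ : dict mapping (variable, band, sex) -> :class:`ImputationModel`
    report_ : DataFrame with one row per stratum × variable.
    """

    def __init__(self, alpha: float = 0.05, min_stratum: int = 30,
                 variables: tuple = VARIABLES, max_redraws: int = 10):
        self.alpha = alpha
        self.min_stratum = min_stratum
        self.variables = variables
        self.max_redraws = max_redraws

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha, "min_stratum": self.min_stratum,
                "variables": self.variables, "max_redraws": self.max_redraws}

    def set_params(self, **params) -> "AnthropometricImputer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- fitting -----------------------------------------------------------

    def fit(self, people: pd.DataFrame) -> "AnthropometricImputer":
        """Fit stratum models on complete cases. ``people`` must carry
        ``age, sex`` and a ``daily_kcal`` column (baseline diary energy)."""
        required = {"age", "sex", "daily_kcal", *self.variables}
        missing = required - set(people.columns)
        if missing:
            raise ValueError(f"people table missing columns: {sorted(missing)}")
        self.models_ = {}
        report_rows = []
        frame = people.assign(band=_impute_band(people["age"]))
        for (band, sex), g in frame.groupby(["band", "sex"], sort=True):
            for var in self.variables:
                complete = g.dropna(subset=[var, "age", "daily_kcal"])
                n_missing = int(g[var].isna().sum())
                model = self._fit_one(var, band, sex, complete)
                self.models_[(var, band, sex)] = model
                report_rows.append({
                    "variable": var, "band": band, "sex": sex,
                    "n_complete": model.n_complete, "n_missing": n_missing,
                    "model": "mean_fallback" if model.fallback
                             else "+".join(model.predictors) or "intercept",
                    "residual_sd": model.residual_sd,
                })
        self.report_ = pd.DataFrame(report_rows)
        return self

    def _fit_one(self, var, band, sex, complete: pd.DataFrame) -> ImputationModel:
        y = complete[var].to_numpy(float)
        if len(complete) < self.min_stratum:
            mean = float(np.mean(y)) if len(y) else float("nan")
            sd = float(np.std(y, ddof=1)) if len(y) > 1 else 0.0
            return ImputationModel(var, band, sex, (), np.array([mean]), sd,
                                   len(complete), fallback=True)
        chosen = None
        with np.errstate(divide="ignore", invalid="ignore"):  # zero-residual fits
            for preds in PREDICTOR_CHAIN:
                X = sm.add_constant(complete[list(preds)].to_numpy(float)) \
                    if preds else np.ones((len(complete), 1))
                fit = sm.OLS(y, X).fit()
                if chosen is None:
                    chosen = (preds, fit)
                    continue
                # LRT of this model against the previously accepted one
                lr = 2 * (fit.llf - chosen[1].llf)
                df = fit.df_model - chosen[1].df_model
                pval = stats.chi2.sf(max(lr, 0.0), df) if np.isfinite(lr) \
                    else (0.0 if lr > 0 else 1.0)
                if pval < self.alpha:
                    chosen = (preds, fit)
                else:
                    break  # forward search stops at the first non-significant term
        preds, fit = chosen
        resid_sd = float(np.sqrt(fit.ssr / fit.df_resid)) if fit.df_resid > 0 else 0.0
        return ImputationModel(var, band, sex, preds, np.asarray(fit.params),
                               resid_sd, len(complete))

    # -- imputation --------------------------------------------------------

    def transform(self, people: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
        """Return a completed copy of ``people``. Observed values and survey
        weights are never altered; each imputed cell is flagged in a
        ``<var>_imputed`` boolean column. Deterministic given ``seed``."""
        if not hasattr(self, "models_"):
            raise RuntimeError("imputer is not fitted; call fit() first")
        rng = np.random.default_rng(seed)
        out = people.copy()
        band = _impute_band(out["age"])
        for var in self.variables:
            out[f"{var}_imputed"] = out[var].isna()
        for (var, b, sex), model in self.models_.items():
            mask = out[var].isna() & (band == b) & (out["sex"] == sex)
            if not mask.any():
                continue
            pred = model.predict(out.loc[mask])
            draws = pred + rng.normal(0.0, model.residual_sd, mask.sum())
            floor = _FLOORS[var]
            for _ in range(self.max_redraws):
                low = draws <= floor
                if not low.any():
                    break
                draws[low] = pred[low] + rng.normal(0.0, model.residual_sd, low.sum())
            draws = np.maximum(draws, floor)
            out.loc[mask, var] = draws
        still = out[list(self.variables)].isna().any(axis=1)
        if still.any():
            raise ValueError(
                f"{int(still.sum())} people left incomplete: no model covers their stratum")
        return out

    def fit_transform(self, people: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
        return self.fit(people).transform(people, seed=seed)


def fit_imputers(people: pd.DataFrame, alpha: float = 0.05,
                 min_stratum: int = 30) -> AnthropometricImputer:
    """Thin functional wrapper: fit an :class:`AnthropometricImputer`."""
    return AnthropometricImputer(alpha=alpha, min_stratum=min_stratum).fit(people)


def impute(people: pd.DataFrame, imputer: AnthropometricImputer,
           seed: int = 0) -> pd.DataFrame:
    """Thin functional wrapper over :meth:`AnthropometricImputer.transform`."""
    return imputer.transform(people, seed=seed)
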