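"""Cox proportional-hazards risk engine.

Fits h(t) = h0(t) exp(beta . z) by maximum partial likelihood (Efron tie
handling, via lifelines) and converts the fit into 5-year absolute risk

    risk% = (1 - S0(5) ^ exp(lp)) * 100,

where S0(5) is the baseline survival at five years from the Breslow
cumulative baseline hazard, anchored at the model's baseline subject: all
centred continuous covariates at zero (i.e. at the fitting sample's means)
and every categorical covariate at its reference level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from scipy import stats

from .design import build_design_matrix
from .errors import DegenerateFitError, FitError, SchemaError

__all__ = [
    "CoxRiskModel",
    "CoxRiskResults",
    "ModelComparison",
    "fit_cox",
    "predict_risk",
    "compare_models",
]

logger = logging.getLogger(__name__)

_SEPARATION_BOUND = 20.0  # |log-HR| beyond this flags monotone likelihood
_SEPARATION_SE_BOUND = 50.0  # a diverging curvature-based SE flags it too


def _lifelines_norm_std(X: pd.DataFrame) -> np.ndarray:
    """Column scales lifelines standardises by (zero-variance columns -> 1)."""
    std = X.std(ddof=1).to_numpy()
    return np.where(std == 0.0, 1.0, std)


class CoxRiskModel:
    """Cox proportional-hazards model of time to first CVD event.

    Parameters
    ----------
    cohort : table with one record per person.  With the default
        ``covariates=None`` the standard risk-factor design matrix is built
        (continuous covariates centred on this sample); passing an explicit
        list of column names uses those columns verbatim (no centring), which
        is how small hand-constructed examples are fitted.
    sbp_column : which SBP recording enters the linear predictor.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        duration_col: str = "time",
        event_col: str = "event",
        covariates: list[str] | None = None,
        sbp_column: str = "sbp",
    ) -> None:
        for col in (duration_col, event_col):
            if col not in cohort.columns:
                raise SchemaError(f"cohort is missing required column: {col}")
        self.cohort = cohort
        self.duration_col = duration_col
        self.event_col = event_col
        self.covariates = covariates
        self.sbp_column = sbp_column
        if covariates is None:
            self._X, self._means = build_design_matrix(cohort, sbp_column=sbp_column)
            # an indicator level with no exposure variation, or with no events
            # among the exposed, makes the partial likelihood monotone in that
            # coefficient; merge such levels into the reference
            events = cohort[event_col].to_numpy(dtype=int)
            drop = []
            for col in self._X.columns:
                x = self._X[col].to_numpy()
                is_indicator = set(np.unique(x)) <= {0.0, 1.0}
                if x.std() == 0.0 or (is_indicator and x[events == 1].sum() == 0):
                    drop.append(col)
            if drop:
                logger.warning(
                    "dropping design column(s) with no usable events: %s", ", ".join(drop)
                )
                self._X = self._X.drop(columns=drop)
        else:
            missing = [c for c in covariates if c not in cohort.columns]
            if missing:
                raise SchemaError(f"cohort is missing covariate(s): {', '.join(missing)}")
            self._X = cohort[covariates].astype(float)
            self._means = {}

    def fit(
        self,
        initial_point: np.ndarray | None = None,
        horizon: float = 5.0,
    ) -> "CoxRiskResults":
        """Fit by maximum partial likelihood (Efron ties) and extract the
        Breslow baseline survival at ``horizon`` years."""
        durations = self.cohort[self.duration_col].to_numpy(dtype=float)
        events = self.cohort[self.event_col].to_numpy(dtype=int)
        n_events = int(events.sum())
        if n_events == 0:
            raise DegenerateFitError("cohort has no events; partial likelihood is degenerate")

        df = self._X.copy()
        df["_T"] = durations
        df["_E"] = events
        if initial_point is not None:
            # lifelines iterates in its internally standardised space
            initial_point = np.asarray(initial_point) * _lifelines_norm_std(self._X)
        cph = CoxPHFitter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cph.fit(df, duration_col="_T", event_col="_E", initial_point=initial_point,
                         fit_options={"precision": 1e-09})
            except ConvergenceError as err:
                raise FitError(f"Cox partial-likelihood fit did not converge: {err}") from err
        del caught  # lifelines' ConvergenceWarnings are heuristic; we test directly below
        betas = cph.params_.copy()
        betas.index = list(self._X.columns)
        ses = pd.Series(cph.standard_errors_.to_numpy(), index=betas.index)
        # monotone likelihood walks a coefficient (and its curvature-based SE)
        # off to infinity; either blowing up flags separation
        if np.any(np.abs(betas.to_numpy()) > _SEPARATION_BOUND) or np.any(
            ses.to_numpy() > _SEPARATION_SE_BOUND
        ):
            worst = betas.abs().idxmax()
            raise FitError(
                f"monotone partial likelihood (separation) suspected for covariate {worst!r}"
            )

        lp = self._X.to_numpy() @ betas.to_numpy()
        s0 = _breslow_baseline_survival(durations, events, lp, horizon)
        return CoxRiskResults(
            betas=betas,
            standard_errors=ses,
            s0_5y=s0,
            centring_means=dict(self._means),
            horizon=horizon,
            model=self,
            fit_meta={
                "n": len(df),
                "events": n_events,
                "converged": True,
                "ties": "efron",
                "log_likelihood": float(cph.log_likelihood_),
            },
        )


def _breslow_baseline_survival(
    durations: np.ndarray, events: np.ndarray, lp: np.ndarray, horizon: float
) -> float:
    """Breslow estimate of S0(horizon) = exp(-H0(horizon)).

    H0(t) = sum over event times t_i <= t of d_i / sum_{j in R(t_i)} exp(lp_j).
    """
    order = np.argsort(durations, kind="stable")
    t = durations[order]
    e = events[order]
    risk = np.exp(lp[order])
    # reverse cumulative sum: total exp(lp) still at risk at each sorted time
    rcum = np.cumsum(risk[::-1])[::-1]
    h0 = 0.0
    i = 0
    n = len(t)
    while i < n and t[i] <= horizon:
        j = i
        d = 0
        while j < n and t[j] == t[i]:
            d += int(e[j])
            j += 1
        if d:
            h0 += d / rcum[i]
        i = j
    return float(np.exp(-h0))


@dataclass
class CoxRiskResults:
    """Fitted Cox model: log-hazard ratios, baseline survival and metadata."""

    betas: pd.Series
    standard_errors: pd.Series
    s0_5y: float
    centring_means: dict[str, float]
    horizon: float
    fit_meta: dict
    model: CoxRiskModel | None = field(default=None, repr=False)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.betas)

    def predict_risk(self, cohort: pd.DataFrame, sbp_column: str | None = None) -> pd.DataFrame:
        """5-year absolute risk (%) for each record, using this fit's
        coefficients, baseline survival and stored centring means."""
        if self.centring_means:
            X, _ = build_design_matrix(
                cohort,
                centring_means=self.centring_means,
                sbp_column=sbp_column or (self.model.sbp_column if self.model else "sbp"),
            )
            X = X[list(self.betas.index)]
        else:
            cols = list(self.betas.index)
            missing = [c for c in cols if c not in cohort.columns]
            if missing:
                raise SchemaError(f"cohort is missing covariate(s): {', '.join(missing)}")
            X = cohort[cols].astype(float)
        lp = X.to_numpy() @ self.betas.to_numpy()
        risk = (1.0 - self.s0_5y ** np.exp(lp)) * 100.0
        out = pd.DataFrame({"risk_percent": np.clip(risk, 0.0, 100.0)}, index=cohort.index)
        if "person_id" in cohort.columns:
            out.insert(0, "person_id", cohort["person_id"].to_numpy())
        return out

    def summary(self) -> pd.DataFrame:
        """Coefficient table: log-HR, SE, HR and 95% HR interval."""
        z = 1.959963984540054
        lo = np.exp(self.betas - z * self.standard_errors)
        hi = np.exp(self.betas + z * self.standard_errors)
        return pd.DataFrame(
            {
                "coef": self.betas,
                "se": self.standard_errors,
                "hr": self.hazard_ratios,
                "hr_lower95": lo,
                "hr_upper95": hi,
            }
        )

    def to_yaml(self, path) -> None:
        payload = {
            "betas": {k: float(v) for k, v in self.betas.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "s0_5y": float(self.s0_5y),
            "centring_means": {k: float(v) for k, v in self.centring_means.items()},
            "horizon": float(self.horizon),
            "fit_meta": self.fit_meta,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CoxRiskResults":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            betas=pd.Series(payload["betas"]),
            standard_errors=pd.Series(payload["standard_errors"]),
            s0_5y=payload["s0_5y"],
            centring_means=payload["centring_means"],
            horizon=payload["horizon"],
            fit_meta=payload["fit_meta"],
        )


@dataclass
class ModelComparison:
    """Per-covariate hazard-ratio comparison of two fits.

    ``relative_difference_percent`` is (HR2 - HR1)/HR1 * 100 per covariate;
    the paired two-sided t-test pairs covariates across the two fits.  When
    the paired differences have zero variance the statistic is undefined and
    p is reported as 1 by convention, flagged via ``degenerate``.
    """

    table: pd.DataFrame
    t_statistic: float
    p_value: float
    max_abs_relative_difference_percent: float
    degenerate: bool = False

    def summary(self) -> pd.DataFrame:
        return self.table


def compare_models(
    fit1: CoxRiskResults, fit2: CoxRiskResults, on: str = "hr"
) -> ModelComparison:
    """Compare two fits covariate-by-covariate (hazard-ratio scale by
    default; ``on='log_hr'`` pairs the coefficients instead)."""
    if list(fit1.betas.index) != list(fit2.betas.index):
        raise SchemaError("fits have mismatched covariate sets")
    hr1 = fit1.hazard_ratios
    hr2 = fit2.hazard_ratios
    rel = (hr2 - hr1) / hr1 * 100.0
    table = pd.DataFrame({"hr_model1": hr1, "hr_model2": hr2,
                          "relative_difference_percent": rel})
    a, b = (fit1.betas, fit2.betas) if on == "log_hr" else (hr1, hr2)
    diffs = (b - a).to_numpy()
    if np.allclose(diffs.std(ddof=1) if len(diffs) > 1 else 0.0, 0.0):
        return ModelComparison(table, float("nan"), 1.0,
                               float(np.max(np.abs(rel))), degenerate=True)
    t_stat, p = stats.ttest_rel(b.to_numpy(), a.to_numpy())
    return ModelComparison(table, float(t_stat), float(p), float(np.max(np.abs(rel))))


def fit_cox(cohort: pd.DataFrame, **kwargs) -> CoxRiskResults:
    """Convenience wrapper: build a :class:`CoxRiskModel` and fit it."""
    fit_kwargs = {}
    for key in ("initial_point", "horizon"):
        if key in kwargs:
            fit_kwargs[key] = kwargs.pop(key)
    return CoxRiskModel(cohort, **kwargs).fit(**fit_kwargs)


def predict_risk(fit: CoxRiskResults, cohort: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Module-level alias for :meth:`CoxRiskResults.predict_risk`."""
    return fit.predict_risk(cohort, **kwargs)
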