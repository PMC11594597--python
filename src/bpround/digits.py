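"""Terminal-digit operations: the zero end-digit rounding operator, the
three-group rounding-prevalence decomposition, and stratified rounding of a
cohort subsample.

Rounding convention (routine manual sphygmomanometry): end-digits 1-4 round
down to the nearest zero end-digit, 6-9 round up, and an end-digit of 5 is
rounded up or down at random with equal probability (configurable).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CONTINUOUS_COLS
from .errors import ConfigurationError, EmptyInputError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "RoundingRule",
    "IDENTITY_RULE",
    "DigitDecomposition",
    "round_to_zero_digit",
    "round_sbp_array",
    "estimate_rounded_fraction",
    "StratificationPlan",
    "stratified_round_sample",
]


@dataclass
class RoundingRule:
    """Stochastic zero end-digit rounding operator.

    Parameters
    ----------
    p_up_at_five : probability that a terminal digit of 5 is rounded up.
    rng_seed : seed of the named rounding stream, so rounding draws are
        reproducible independently of all other pipeline randomness.
    delta_scale : attenuation hook for sensitivity analysis: the signed
        rounding displacement is multiplied by this factor (0 disables
        rounding entirely, 1 is the standard rule).  For values strictly
        between 0 and 1 the recorded value need not end in zero.
    """

    p_up_at_five: float = 0.5
    rng_seed: int = 0
    delta_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_up_at_five <= 1.0:
            raise ConfigurationError("p_up_at_five must be in [0, 1]")
        if self.delta_scale < 0.0:
            raise ConfigurationError("delta_scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    @property
    def is_identity(self) -> bool:
        return self.delta_scale == 0.0


#: rule whose application leaves every recording unchanged
IDENTITY_RULE = RoundingRule(delta_scale=0.0)


def round_sbp_array(
    sbp: np.ndarray, rule: RoundingRule, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Vectorised zero end-digit rounding of integer SBP values (mmHg)."""
    sbp = np.asarray(sbp)
    if sbp.size and not np.issubdtype(sbp.dtype, np.integer):
        as_int = sbp.astype(np.int64)
        if not np.array_equal(as_int, sbp):
            raise InputError("sbp values must be integers (mmHg)")
        sbp = as_int
    if np.any(sbp <= 0):
        raise InputError("sbp values must be positive")
    if rng is None:
        rng = rule.rng()

    d = sbp % 10
    delta = np.where(d <= 4, -d, 10 - d).astype(np.int64)
    fives = d == 5
    if fives.any():
        up = rng.random(int(fives.sum())) < rule.p_up_at_five
        delta[fives] = np.where(up, 5, -5)
    if rule.delta_scale != 1.0:
        delta = np.rint(rule.delta_scale * delta).astype(np.int64)
    return sbp + delta


def round_to_zero_digit(
    sbp: int, rule: RoundingRule, rng: np.random.Generator | None = None
) -> int:
    """Round one SBP recording to the nearest zero end-digit.

    The result always ends in 0, moves by at most 5 mmHg, and equals the
    input exactly when the input already ends in 0.
    """
    if isinstance(sbp, (bool, str)) or not isinstance(sbp, (int, float, np.integer, np.floating)):
        raise InputError(f"sbp must be a positive integer, got {sbp!r}")
    if not float(sbp).is_integer():
        raise InputError(f"sbp must be a positive integer, got {sbp!r}")
    return int(round_sbp_array(np.array([int(sbp)]), rule, rng)[0])


@dataclass(frozen=True)
class DigitDecomposition:
    """Three-group decomposition of zero end-digit prevalence.

    Splits recordings into (1) non-zero end-digits, (2) true zero end-digits
    expected from unbiased recording on an even-number calibration grid
    (20% by default), and (3) excess zeros attributed to rounding.
    """

    p_zero_observed: float
    p_zero_true: float
    rounded_fraction_estimate: float
    deficit_warning: bool = False

    @property
    def p_nonzero(self) -> float:
        return 1.0 - self.p_zero_observed


def estimate_rounded_fraction(
    p_zero_observed: float,
    p_zero_true: float = 0.20,
    mixture_consistent: bool = False,
) -> DigitDecomposition:
    """Estimate the fraction of the cohort whose SBP was rounded to a zero
    end-digit, from observed and expected zero end-digit prevalence.

    The default estimator is the literal excess ``p_obs - p_true`` (clamped
    at zero).  With ``mixture_consistent=True`` the estimate inverts the
    recording mixture instead: ``(p_obs - p_true) / (1 - p_true)``, which
    accounts for rounded values that would have ended in zero anyway.
    """
    for name, p in (("p_zero_observed", p_zero_observed), ("p_zero_true", p_zero_true)):
        if not 0.0 <= p <= 1.0:
            raise InputError(f"{name} must be in [0, 1], got {p}")
    excess = p_zero_observed - p_zero_true
    deficit = excess < 0
    if deficit:
        warnings.warn(
            "observed zero end-digit prevalence is below the unbiased-recording "
            "expectation; rounded fraction clamped to 0",
            stacklevel=2,
        )
    if mixture_consistent and p_zero_true < 1.0:
        estimate = max(0.0, excess / (1.0 - p_zero_true))
    else:
        estimate = max(0.0, excess)
    return DigitDecomposition(p_zero_observed, p_zero_true, estimate, deficit)


@dataclass
class StratificationPlan:
    """Stratified-sampling plan used to generalise rounding to a cohort.

    Strata are the cross-classification of quantile bins of the continuous
    variables with the levels of the categorical variables, computed over the
    non-zero end-digit subset.  Defaults stratify on quintiles of age and SBP
    crossed with sex and diabetes.
    """

    strata_variables: list[str] = field(default_factory=lambda: ["age", "sbp", "sex", "diabetes"])
    n_quantiles: int = 5
    sample_fraction: float = 0.15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sample_fraction <= 1.0:
            raise ConfigurationError("sample_fraction must be in [0, 1]")
        if self.n_quantiles < 2:
            raise ConfigurationError("n_quantiles must be >= 2")
        if not self.strata_variables:
            raise ConfigurationError("strata_variables must be non-empty")


def stratified_round_sample(
    cohort: pd.DataFrame, plan: StratificationPlan, rule: RoundingRule
) -> pd.DataFrame:
    """Round the SBP of a stratified subsample of the non-zero end-digit records.

    Within each stratum a simple random sample of ``round(sample_fraction x
    stratum size)`` records (without replacement, stable record order) has its
    SBP replaced by the zero end-digit rounding of the current value.  All
    other records are returned unchanged.  The centred SBP column, when
    present, is recomputed on the returned table.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort is empty")
    missing = [v for v in plan.strata_variables if v not in cohort.columns]
    if missing:
        raise InputError(f"strata variable(s) not in cohort: {', '.join(missing)}")

    out = cohort.copy()
    nonzero = out.index[out["sbp"].astype(int) % 10 != 0]
    if len(nonzero) == 0:
        raise EmptyInputError("no non-zero end-digit SBP records to sample from")

    sub = out.loc[nonzero]
    keys = []
    for var in plan.strata_variables:
        if var in CONTINUOUS_COLS or pd.api.types.is_float_dtype(sub[var]):
            binned = pd.qcut(sub[var].rank(method="first"), plan.n_quantiles, labels=False)
            keys.append(binned.astype(int).astype(str))
        else:
            keys.append(sub[var].astype(str))
    stratum = keys[0]
    for k in keys[1:]:
        stratum = stratum + "|" + k

    rng = np.random.default_rng(plan.rng_seed)
    round_rng = rule.rng()
    chosen: list[np.ndarray] = []
    for label, idx in sub.groupby(stratum.values).groups.items():
        m = len(idx)
        if m == 0:  # pragma: no cover - groupby never yields empty groups
            logger.info("stratum %s empty; skipped", label)
            continue
        k = int(np.floor(plan.sample_fraction * m + 0.5))
        if k > 0:
            take = rng.choice(np.asarray(idx), size=k, replace=False)
            chosen.append(take)
    if chosen:
        sel = np.concatenate(chosen)
        out.loc[sel, "sbp"] = round_sbp_array(
            out.loc[sel, "sbp"].to_numpy(dtype=np.int64), rule, round_rng
        )
    if "sbp_c" in out.columns:
        out["sbp_c"] = out["sbp"] - out["sbp"].mean()
    return out
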