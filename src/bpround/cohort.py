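"""Synthetic primary-care CVD cohort generator.

The real risk-assessment cohort this package emulates is access-restricted,
so every downstream stage is exercised on synthetic cohorts that reproduce
the statistical structure the analysis depends on:

* a mixture terminal-digit distribution for recorded SBP — a latent
  continuous pressure quantised to the device calibration grid (1 or 2 mmHg),
  with a configurable fraction of people whose recording is additionally
  rounded to a zero end-digit;
* survival times from a proportional-hazards model with known log-hazard
  ratios, driven by the *latent* (unrounded) SBP so that rounding is purely a
  recording error;
* independent censoring (administrative at 5 years plus optional random
  exponential censoring);
* a risk distribution dominated by the low-risk (<5% 5-year risk) group.

The default log-hazard ratios are plausible-magnitude placeholders for a
primary-prevention CVD equation; they are NOT the (unpublished) coefficients
of any national risk equation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .design import BMI_LEVELS, ETHNICITY_LEVELS, build_design_matrix
from .digits import RoundingRule, round_sbp_array
from .errors import ConfigurationError, EmptyInputError

__all__ = [
    "GeneratorConfig",
    "DEFAULT_TRUE_BETAS",
    "DEFAULT_COVARIATE_PREVALENCES",
    "generate_cohort",
    "digit_distribution",
    "write_cohort",
    "read_cohort",
    "COHORT_COLUMNS",
]

#: default log-hazard ratios, keyed by design-matrix column.  Plausible
#: magnitudes for a 5-year primary-prevention CVD equation; continuous terms
#: are per unit (years, mmHg, ratio units) on the centred scale.
DEFAULT_TRUE_BETAS: dict[str, float] = {
    "age_c": 0.075,
    "eth_maori": 0.25,
    "eth_pacific": 0.15,
    "eth_indian": 0.25,
    "eth_asian": -0.25,
    "nzdep_2": 0.05,
    "nzdep_3": 0.10,
    "nzdep_4": 0.15,
    "nzdep_5": 0.25,
    "ex_smoker": 0.12,
    "current_smoker": 0.55,
    "family_history": 0.15,
    "atrial_fibrillation": 0.85,
    "diabetes": 0.50,
    "sbp_c": 0.013,
    "tchdl_c": 0.16,
    "bmi_underweight": 0.30,
    "bmi_overweight": 0.05,
    "bmi_obesity1": 0.10,
    "bmi_obesity2": 0.15,
    "bmi_obesity3": 0.25,
    "bmi_unknown": 0.10,
    "bp_med": 0.20,
    "lipid_med": 0.10,
    "antithrombotic_med": 0.15,
}

#: marginal covariate prevalences (whole-cohort margins of the emulated
#: population); categorical entries are level -> probability mappings.
DEFAULT_COVARIATE_PREVALENCES: dict = {
    "ethnicity": {
        "European": 0.567,
        "Maori": 0.137,
        "Pacific": 0.147,
        "Indian": 0.083,
        "Chinese/other Asian": 0.066,
    },
    "nzdep": {1: 0.221, 2: 0.197, 3: 0.178, 4: 0.183, 5: 0.221},
    "ex_smoker": 0.172,
    "current_smoker": 0.150,
    "family_history": 0.106,
    "atrial_fibrillation": 0.014,
    "diabetes": 0.109,
    "bmi_class": {
        "normal": 0.2025,
        "underweight": 0.0062,
        "overweight": 0.3004,
        "obesity class 1": 0.1791,
        "obesity class 2": 0.0805,
        "obesity class 3": 0.0562,
        "bmi unknown": 0.1751,
    },
    "bp_med": 0.234,
    "lipid_med": 0.167,
    "antithrombotic_med": 0.102,
    "prior_cvd": 0.05,
}

COHORT_COLUMNS = [
    "person_id",
    "sex",
    "age",
    "age_c",
    "ethnicity",
    "nzdep",
    "ex_smoker",
    "current_smoker",
    "family_history",
    "atrial_fibrillation",
    "diabetes",
    "sbp",
    "sbp_c",
    "tchdl",
    "tchdl_c",
    "bmi_class",
    "bp_med",
    "lipid_med",
    "antithrombotic_med",
    "event",
    "time",
    "prior_cvd",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    ``age_by_sex`` holds (mean, sd) of age in years per sex; latent SBP is
    Normal(``sbp_mean``, ``sbp_sd``) truncated to [70, 250] mmHg and quantised
    to the ``calibration_step`` grid; a Bernoulli(``rounded_fraction``) subset
    is then re-recorded with zero end-digit rounding.  Survival uses a
    Weibull baseline with scale ``baseline_hazard_rate`` (events per
    person-year; ``weibull_shape=1`` gives the constant-hazard exponential
    default).

    The default grid is 1 mmHg — integer recordings with all ten terminal
    digits present, as the rounding rule's random digit-5 resolution
    presupposes — and the default ``rounded_fraction`` of 0.25 yields an
    observed zero end-digit share of about 0.1 x 0.75 + 0.25 = 32.5%,
    matching the prevalence the analysis is designed around.  Set
    ``calibration_step=2`` with ``rounded_fraction=0`` to emulate unbiased
    recording on an even-number grid (about 20% zero end-digits).
    """

    n_people: int = 40_000
    sex_fraction_male: float = 0.564
    true_betas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_BETAS))
    baseline_hazard_rate: float = 0.008
    admin_censor_time: float = 5.0
    random_censor_rate: float = 0.02
    sbp_mean: float = 130.0
    sbp_sd: float = 16.0
    rounded_fraction: float = 0.25
    calibration_step: int = 1
    covariate_prevalences: Mapping = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES)
    )
    weibull_shape: float = 1.0
    age_by_sex: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"M": (51.29, 10.07), "F": (55.85, 8.87)}
    )
    tchdl_mean: float = 3.6
    tchdl_sd: float = 1.0
    p_up_at_five: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_people <= 0:
            raise ConfigurationError("n_people must be a positive integer")
        for name in ("sex_fraction_male", "rounded_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_hazard_rate", "admin_censor_time", "sbp_sd", "tchdl_sd",
                     "weibull_shape"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.random_censor_rate < 0:
            raise ConfigurationError("random_censor_rate must be >= 0")
        if self.calibration_step not in (1, 2):
            raise ConfigurationError("calibration_step must be 1 or 2")
        for key in ("ethnicity", "nzdep", "bmi_class"):
            probs = self.covariate_prevalences[key]
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"covariate_prevalences[{key!r}] must sum to 1")


def _draw_categorical(rng: np.random.Generator, mapping: Mapping, n: int) -> np.ndarray:
    levels = list(mapping)
    p = np.array([mapping[k] for k in levels], dtype=float)
    return rng.choice(np.array(levels, dtype=object), size=n, p=p / p.sum())


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table.

    Returns a DataFrame with one record per person (columns per
    :data:`COHORT_COLUMNS` plus ``sbp_true``, the latent pre-rounding SBP
    kept for diagnostics).  Reproducible under a fixed ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    cov_rng, surv_rng, round_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    n = config.n_people
    prev = config.covariate_prevalences

    n_male = int(round(config.sex_fraction_male * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male), dtype=object)

    age = np.empty(n)
    for s in ("M", "F"):
        mask = sex == s
        mu, sd = config.age_by_sex[s]
        age[mask] = np.clip(cov_rng.normal(mu, sd, int(mask.sum())), 30.0, 80.0)

    ethnicity = _draw_categorical(cov_rng, prev["ethnicity"], n)
    nzdep = _draw_categorical(cov_rng, prev["nzdep"], n).astype(int)

    # mutually exclusive smoking status
    u = cov_rng.random(n)
    current_smoker = (u < prev["current_smoker"]).astype(int)
    ex_smoker = ((u >= prev["current_smoker"])
                 & (u < prev["current_smoker"] + prev["ex_smoker"])).astype(int)

    flags = {}
    for name in ("family_history", "atrial_fibrillation", "diabetes",
                 "bp_med", "lipid_med", "antithrombotic_med", "prior_cvd"):
        flags[name] = (cov_rng.random(n) < prev[name]).astype(int)

    bmi_class = _draw_categorical(cov_rng, prev["bmi_class"], n)

    tchdl = np.clip(cov_rng.normal(config.tchdl_mean, config.tchdl_sd, n), 1.0, 12.0)

    # latent SBP: truncated normal, then calibration-grid quantisation
    a = (70.0 - config.sbp_mean) / config.sbp_sd
    b = (250.0 - config.sbp_mean) / config.sbp_sd
    latent = stats.truncnorm.rvs(
        a, b, loc=config.sbp_mean, scale=config.sbp_sd, size=n, random_state=cov_rng
    )
    step = config.calibration_step
    sbp_true = (step * np.rint(latent / step)).astype(np.int64)
    sbp_true = np.clip(sbp_true, step, None)

    rounded = round_rng.random(n) < config.rounded_fraction
    sbp = sbp_true.copy()
    if rounded.any():
        rule = RoundingRule(p_up_at_five=config.p_up_at_five, rng_seed=0)
        sbp[rounded] = round_sbp_array(sbp_true[rounded], rule, round_rng)

    df = pd.DataFrame(
        {
            "person_id": np.arange(n),
            "sex": sex,
            "age": age,
            "ethnicity": pd.Categorical(ethnicity, categories=ETHNICITY_LEVELS),
            "nzdep": nzdep,
            "ex_smoker": ex_smoker,
            "current_smoker": current_smoker,
            "family_history": flags["family_history"],
            "atrial_fibrillation": flags["atrial_fibrillation"],
            "diabetes": flags["diabetes"],
            "sbp": sbp,
            "tchdl": tchdl,
            "bmi_class": pd.Categorical(bmi_class, categories=BMI_LEVELS),
            "bp_med": flags["bp_med"],
            "lipid_med": flags["lipid_med"],
            "antithrombotic_med": flags["antithrombotic_med"],
            "prior_cvd": flags["prior_cvd"],
        }
    )
    df["sbp_true"] = sbp_true

    # hazard from the latent (unrounded) SBP: rounding is recording error only
    X, _ = build_design_matrix(df, sbp_column="sbp_true")
    beta = np.array([config.true_betas.get(c, 0.0) for c in X.columns])
    lp = X.to_numpy() @ beta

    rate = config.baseline_hazard_rate * np.exp(lp)
    e = surv_rng.exponential(1.0, n)
    if config.weibull_shape == 1.0:
        t_event = e / rate
    else:
        t_event = (e / rate) ** (1.0 / config.weibull_shape)
    if config.random_censor_rate > 0:
        c_rand = surv_rng.exponential(1.0 / config.random_censor_rate, n)
    else:
        c_rand = np.full(n, np.inf)
    censor = np.minimum(c_rand, config.admin_censor_time)
    df["time"] = np.maximum(np.minimum(t_event, censor), 1e-9)
    df["event"] = (t_event <= censor).astype(int)

    # centred copies (whole-sample centring)
    df["age_c"] = df["age"] - df["age"].mean()
    df["sbp_c"] = df["sbp"] - df["sbp"].mean()
    df["tchdl_c"] = df["tchdl"] - df["tchdl"].mean()
    return df[COHORT_COLUMNS + ["sbp_true"]]


def digit_distribution(cohort: pd.DataFrame) -> dict[int, float]:
    """Proportion of recorded SBP values by terminal digit (0-9).

    Only digits present in the data appear as non-zero entries; proportions
    sum to 1.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort is empty")
    digits = cohort["sbp"].astype(int) % 10
    counts = digits.value_counts(normalize=True)
    return {int(d): float(counts.get(d, 0.0)) for d in range(10)}


def write_cohort(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a cohort as comma-delimited text with a one-line ``#`` metadata header."""
    with open(path, "w") as fh:
        meta = f"# bpround cohort v1"
        if seed is not None:
            meta += f" seed={seed}"
        fh.write(meta + "\n")
        cohort.to_csv(fh, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort` (``#`` lines ignored)."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise EmptyInputError(f"cohort file {path} is empty")
    return pd.read_csv(io.StringIO(text), comment="#")
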