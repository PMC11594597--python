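"""Monte-Carlo misclassification experiment.

The core procedure: on the subset of people with no prior CVD and a non-zero
SBP end-digit, fit a Cox model (Model 1) and compute each person's 5-year
risk and risk category; then, repeatedly, round every SBP to the nearest
zero end-digit (digit 5 resolved at random each repetition), refit (Model 2),
recompute risk, and cross-tabulate original versus post-rounding categories.
The 3x3 confusion matrices are averaged over repetitions with percentile 95%
confidence intervals.  Sexes are always analysed separately.

Risk categories follow the NZ CVD management guidelines: low < 5%,
moderate 5-15% (closed interval), high > 15% 5-year risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .cox import (
    CoxRiskModel,
    CoxRiskResults,
    ModelComparison,
    _breslow_baseline_survival,
    _lifelines_norm_std,
    compare_models,
)
from .digits import DigitDecomposition, RoundingRule, round_sbp_array
from .errors import InputError, UndefinedScalingError

logger = logging.getLogger(__name__)

__all__ = [
    "CATEGORY_LABELS",
    "categorize",
    "categorize_array",
    "SimulationConfig",
    "MisclassificationResult",
    "RoundingExperiment",
    "RoundingExperimentResults",
    "run_rounding_experiment",
    "convergence_table",
    "convergence_diagnostic",
    "GeneralizedCounts",
    "generalize_to_cohort",
]

CATEGORY_LABELS = ["low", "moderate", "high"]


def categorize_array(risk_percent: np.ndarray) -> np.ndarray:
    """Vectorised category codes (0 low, 1 moderate, 2 high)."""
    r = np.asarray(risk_percent, dtype=float)
    if np.any((r < 0) | (r > 100)) or np.any(np.isnan(r)):
        raise InputError("risk_percent values must be in [0, 100]")
    return np.where(r < 5.0, 0, np.where(r <= 15.0, 1, 2))


def categorize(risk_percent: float) -> str:
    """Risk category of one 5-year risk percentage: low < 5 <= moderate <= 15 < high."""
    return CATEGORY_LABELS[int(categorize_array(np.array([risk_percent]))[0])]


@dataclass
class SimulationConfig:
    """Controls of the rounding experiment.

    ``n_simulations`` defaults to the full 10,000-repetition design; desk
    profiles pass a smaller count.  ``refit_per_simulation=False`` keeps
    Model 1's coefficients and baseline and only re-evaluates the linear
    predictor on the rounded SBP (fast path, used for perturbation studies).
    """

    n_simulations: int = 10_000
    rng_seed: int = 0
    refit_per_simulation: bool = True
    convergence_grid: tuple[int, ...] = (10, 100, 1000, 5000, 10_000, 15_000)

    def __post_init__(self) -> None:
        if self.n_simulations < 1:
            raise InputError("n_simulations must be >= 1")
        if list(self.convergence_grid) != sorted(self.convergence_grid):
            raise InputError("convergence_grid must be increasing")


@dataclass
class MisclassificationResult:
    """Per-sex misclassification summary across simulations.

    ``mean_matrix`` rows index the original category, columns the
    post-rounding category; each row sums to that row's original-category
    count.  CIs are percentile (2.5th/97.5th) across simulations.
    """

    sex: str
    mean_matrix: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_simulations: int
    n_dropped: int
    original_counts: np.ndarray
    sim_matrices: np.ndarray = field(repr=False)
    n_subjects: int = 0
    n_rounded: int = 0

    @property
    def undertreated(self) -> float:
        """Mean count misclassified moderate -> low."""
        return float(self.mean_matrix[1, 0])

    @property
    def overtreated_to_moderate(self) -> float:
        """Mean count misclassified low -> moderate."""
        return float(self.mean_matrix[0, 1])

    @property
    def overtreated_to_high(self) -> float:
        """Mean count misclassified moderate -> high."""
        return float(self.mean_matrix[1, 2])

    @property
    def row_percentages(self) -> np.ndarray:
        """Cells as percentages of their row's original-category count."""
        totals = self.original_counts.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(totals[:, None] > 0, self.mean_matrix / totals[:, None] * 100.0, 0.0)
        return pct

    @property
    def percent_correct_per_sim(self) -> np.ndarray:
        total = self.sim_matrices.sum(axis=(1, 2))
        diag = self.sim_matrices[:, [0, 1, 2], [0, 1, 2]].sum(axis=1)
        return diag / total * 100.0

    def to_frame(self) -> pd.DataFrame:
        """Confusion matrix with CIs in a printable layout."""
        rows = {}
        for i, orig in enumerate(CATEGORY_LABELS):
            rows[orig] = {
                new: f"{self.mean_matrix[i, j]:.1f} ({self.ci_lower[i, j]:.0f}-{self.ci_upper[i, j]:.0f})"
                for j, new in enumerate(CATEGORY_LABELS)
            }
            rows[orig]["total"] = int(self.original_counts[i])
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            f"Misclassification, sex={self.sex} "
            f"({self.n_simulations} simulations, {self.n_dropped} dropped)",
            self.to_frame().to_string(),
            f"undertreated (moderate->low): {self.undertreated:.1f}",
            f"overtreated (low->moderate): {self.overtreated_to_moderate:.1f}",
            f"overtreated (moderate->high): {self.overtreated_to_high:.1f}",
        ]
        return "\n".join(lines)


class RoundingExperiment:
    """Rounding-misclassification experiment on one cohort.

    Built from a cohort table, a :class:`RoundingRule` and a
    :class:`SimulationConfig`; :meth:`fit` runs the simulations per sex and
    returns a :class:`RoundingExperimentResults`.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        rule: RoundingRule | None = None,
        config: SimulationConfig | None = None,
        sexes: tuple[str, ...] = ("M", "F"),
    ) -> None:
        self.cohort = cohort
        self.rule = rule if rule is not None else RoundingRule()
        self.config = config if config is not None else SimulationConfig()
        self.sexes = sexes

    def modelling_subset(self, sex: str) -> pd.DataFrame:
        """People of the given sex with no prior CVD and a non-zero SBP end-digit."""
        c = self.cohort
        mask = (c["sex"] == sex) & (c["prior_cvd"] == 0) & (c["sbp"].astype(int) % 10 != 0)
        return c.loc[mask].reset_index(drop=True)

    def fit(self) -> "RoundingExperimentResults":
        results: dict[str, MisclassificationResult] = {}
        comparisons: dict[str, ModelComparison] = {}
        model1_fits: dict[str, CoxRiskResults] = {}
        for s_index, sex in enumerate(self.sexes):
            subset = self.modelling_subset(sex)
            if len(subset) == 0 or subset["event"].sum() == 0:
                logger.warning("sex stratum %s has no events; skipped", sex)
                continue
            res, comp, fit1 = self._run_sex(subset, sex, s_index)
            results[sex] = res
            comparisons[sex] = comp
            model1_fits[sex] = fit1
        return RoundingExperimentResults(results, comparisons, model1_fits, self.config)

    def _run_sex(self, subset: pd.DataFrame, sex: str, sex_index: int):
        cfg = self.config
        model1 = CoxRiskModel(subset)
        fit1 = model1.fit()
        risk1 = fit1.predict_risk(subset)["risk_percent"].to_numpy()
        cat1 = categorize_array(risk1)
        orig_counts = np.bincount(cat1, minlength=3)

        X = model1._X.copy()
        durations = subset["time"].to_numpy(dtype=float)
        events = subset["event"].to_numpy(dtype=int)
        sbp0 = subset["sbp"].to_numpy(dtype=np.int64)
        beta1 = fit1.betas.to_numpy()
        sbp_pos = list(X.columns).index("sbp_c")

        children = np.random.SeedSequence([cfg.rng_seed, sex_index]).spawn(cfg.n_simulations)
        matrices = []
        dropped = 0
        fit2_first: CoxRiskResults | None = None

        fit_df = X.copy()
        fit_df["_T"] = durations
        fit_df["_E"] = events
        Xv = X.to_numpy()
        warm_scale = _lifelines_norm_std(X)

        for b in range(cfg.n_simulations):
            rng = np.random.default_rng(children[b])
            sbp_b = round_sbp_array(sbp0, self.rule, rng)
            if cfg.refit_per_simulation:
                sbp_c_b = sbp_b - sbp_b.mean()
                fit_df["sbp_c"] = sbp_c_b
                cph = CoxPHFitter()
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        cph.fit(fit_df, duration_col="_T", event_col="_E",
                                initial_point=beta1 * warm_scale,
                                fit_options={"precision": 1e-09})
                except ConvergenceError:
                    dropped += 1
                    logger.warning("simulation %d (%s): refit did not converge; dropped", b, sex)
                    continue
                beta_b = cph.params_.to_numpy()
                Xb = Xv.copy()
                Xb[:, sbp_pos] = sbp_c_b
                lp = Xb @ beta_b
                s0_b = _breslow_baseline_survival(durations, events, lp, fit1.horizon)
                if fit2_first is None:
                    fit2_first = CoxRiskResults(
                        betas=pd.Series(beta_b, index=X.columns),
                        standard_errors=pd.Series(cph.standard_errors_.to_numpy(),
                                                  index=X.columns),
                        s0_5y=s0_b,
                        centring_means={**fit1.centring_means, "sbp": float(sbp_b.mean())},
                        horizon=fit1.horizon,
                        fit_meta={"n": len(subset), "events": int(events.sum()),
                                  "converged": True, "ties": "efron"},
                    )
            else:
                # keep Model 1; only the SBP contribution to the lp changes
                lp0 = Xv @ beta1
                lp = lp0 + beta1[sbp_pos] * (sbp_b - sbp0)
                s0_b = fit1.s0_5y
            risk2 = np.clip((1.0 - s0_b ** np.exp(lp)) * 100.0, 0.0, 100.0)
            cat2 = categorize_array(risk2)
            matrices.append(np.bincount(cat1 * 3 + cat2, minlength=9).reshape(3, 3))

        sims = np.array(matrices, dtype=np.int64)
        mean = sims.mean(axis=0)
        lo = np.percentile(sims, 2.5, axis=0)
        hi = np.percentile(sims, 97.5, axis=0)
        result = MisclassificationResult(
            sex=sex,
            mean_matrix=mean,
            ci_lower=lo,
            ci_upper=hi,
            n_simulations=len(sims),
            n_dropped=dropped,
            original_counts=orig_counts,
            sim_matrices=sims,
            n_subjects=len(subset),
            n_rounded=len(subset),
        )
        if fit2_first is None:
            fit2_first = fit1
        comp = compare_models(fit1, fit2_first)
        return result, comp, fit1


@dataclass
class RoundingExperimentResults:
    """Per-sex misclassification results plus the representative Model 1 vs
    Model 2 hazard-ratio comparison."""

    results: dict[str, MisclassificationResult]
    comparisons: dict[str, ModelComparison]
    model1_fits: dict[str, CoxRiskResults]
    config: SimulationConfig

    def __getitem__(self, sex: str) -> MisclassificationResult:
        return self.results[sex]

    def summary(self) -> str:
        parts = []
        for sex, res in self.results.items():
            parts.append(res.summary())
            comp = self.comparisons[sex]
            parts.append(
                f"Model 1 vs Model 2 ({sex}): max |relative HR difference| = "
                f"{comp.max_abs_relative_difference_percent:.3f}%, "
                f"paired t-test p = {comp.p_value:.3f}"
                + (" (degenerate)" if comp.degenerate else "")
            )
        return "\n\n".join(parts)


def run_rounding_experiment(
    cohort: pd.DataFrame,
    rule: RoundingRule | None = None,
    sim: SimulationConfig | None = None,
    sexes: tuple[str, ...] = ("M", "F"),
) -> RoundingExperimentResults:
    """Functional wrapper over :class:`RoundingExperiment`."""
    return RoundingExperiment(cohort, rule, sim, sexes).fit()


def convergence_table(result: MisclassificationResult, grid) -> pd.DataFrame:
    """Stability of the percent-correctly-classified statistic by simulation
    count: mean over the first B simulations with a normal-approximation 95%
    CI of the mean (width shrinks ~ 1/sqrt(B))."""
    if len(grid) == 0:
        raise InputError("convergence grid is empty")
    pc = result.percent_correct_per_sim
    rows = []
    for b in grid:
        b_eff = min(int(b), len(pc))
        sample = pc[:b_eff]
        m = float(sample.mean())
        se = float(sample.std(ddof=1) / np.sqrt(b_eff)) if b_eff > 1 else 0.0
        rows.append(
            {
                "n_simulations": b_eff,
                "percent_correct": m,
                "ci_lower": m - 1.96 * se,
                "ci_upper": m + 1.96 * se,
                "ci_width": 2 * 1.96 * se,
            }
        )
    return pd.DataFrame(rows)


def convergence_diagnostic(
    cohort: pd.DataFrame,
    rule: RoundingRule,
    grid,
    config: SimulationConfig | None = None,
    sex: str = "F",
) -> pd.DataFrame:
    """Run the experiment with max(grid) simulations for one sex and report
    classification-accuracy stability across the grid."""
    if len(grid) == 0:
        raise InputError("convergence grid is empty")
    base = config if config is not None else SimulationConfig()
    cfg = SimulationConfig(
        n_simulations=int(max(grid)),
        rng_seed=base.rng_seed,
        refit_per_simulation=base.refit_per_simulation,
        convergence_grid=tuple(sorted(int(g) for g in grid)),
    )
    res = RoundingExperiment(cohort, rule, cfg, sexes=(sex,)).fit()
    return convergence_table(res[sex], cfg.convergence_grid)


@dataclass
class GeneralizedCounts:
    """Whole-cohort under/over-treatment counts scaled from the experiment."""

    per_sex: dict[str, dict[str, int]]
    scaling_factors: dict[str, float]

    @property
    def undertreated_total(self) -> int:
        return sum(d["undertreated"] for d in self.per_sex.values())

    @property
    def overtreated_total(self) -> int:
        return sum(d["overtreated_to_moderate"] + d["overtreated_to_high"]
                   for d in self.per_sex.values())


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def generalize_to_cohort(
    results: dict[str, MisclassificationResult],
    decomposition: DigitDecomposition,
    cohort_sizes: dict[str, int],
    scaling_factor: float | None = None,
) -> GeneralizedCounts:
    """Scale subset-level misclassification totals to the whole cohort.

    The experiment rounds every non-zero end-digit SBP; in the whole cohort
    only an estimated ``decomposition.rounded_fraction_estimate`` of records
    are rounded.  Per sex the totals are multiplied by

        factor = rounded_fraction_estimate / (n_rounded_in_experiment / cohort size)

    unless an explicit ``scaling_factor`` is supplied.  Results are rounded
    half away from zero.
    """
    per_sex = {}
    factors = {}
    for sex, res in results.items():
        if scaling_factor is None:
            if res.n_rounded == 0:
                raise UndefinedScalingError(
                    f"experiment for sex {sex} rounded no records; scaling undefined"
                )
            exp_fraction = res.n_rounded / cohort_sizes[sex]
            factor = decomposition.rounded_fraction_estimate / exp_fraction
        else:
            factor = scaling_factor
        if factor == 0.0:
            warnings.warn(f"scaling factor for sex {sex} is zero; counts are all zero",
                          stacklevel=2)
        factors[sex] = factor
        logger.info("generalization scaling factor for %s: %.4f", sex, factor)
        per_sex[sex] = {
            "undertreated": _round_half_away(res.undertreated * factor),
            "overtreated_to_moderate": _round_half_away(res.overtreated_to_moderate * factor),
            "overtreated_to_high": _round_half_away(res.overtreated_to_high * factor),
        }
    return GeneralizedCounts(per_sex, factors)
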