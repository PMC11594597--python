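"""End-to-end orchestration: cohort -> digit audit -> per-sex rounding
experiment -> whole-cohort generalization -> cost model -> report.

A single master seed deterministically derives every module's RNG substream,
so a run is reproducible from its config echo alone.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    COHORT_COLUMNS,
    GeneratorConfig,
    digit_distribution,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .costs import CostSchedule, misclassification_cost
from .design import BMI_LEVELS, ETHNICITY_LEVELS
from .digits import RoundingRule, StratificationPlan, estimate_rounded_fraction
from .errors import BProundError, ConfigurationError, EmptyInputError, SchemaError
from .experiment import (
    RoundingExperiment,
    SimulationConfig,
    convergence_table,
    generalize_to_cohort,
)
from .report import summarize_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis", "validate_cohort_file"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of ``generator`` / ``cohort_path`` supplies the cohort.  When
    ``master_seed`` is set it deterministically derives the generator,
    rounding, simulation and stratification seeds (overriding theirs).
    """

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    rule: RoundingRule = field(default_factory=RoundingRule)
    sim: SimulationConfig = field(default_factory=lambda: SimulationConfig(n_simulations=200))
    plan: StratificationPlan = field(default_factory=StratificationPlan)
    cost_schedule_path: str | None = None
    out_dir: str = "bpround_run"
    master_seed: int | None = None
    p_zero_true: float = 0.20
    verbosity: int = 1

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.cohort_path is None):
            raise ConfigurationError(
                "exactly one cohort source required: set generator or cohort_path"
            )
        if self.master_seed is not None:
            ss = np.random.SeedSequence(self.master_seed)
            seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
            if self.generator is not None:
                self.generator.seed = seeds[0]
            self.rule = dataclasses.replace(self.rule, rng_seed=seeds[1])
            self.sim = dataclasses.replace(self.sim, rng_seed=seeds[2])
            self.plan = dataclasses.replace(self.plan, rng_seed=seeds[3])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "generator" in raw:
            kwargs["generator"] = GeneratorConfig(**raw["generator"])
        if "rounding" in raw:
            kwargs["rule"] = RoundingRule(**raw["rounding"])
        if "simulation" in raw:
            kwargs["sim"] = SimulationConfig(**raw["simulation"])
        if "stratification" in raw:
            kwargs["plan"] = StratificationPlan(**raw["stratification"])
        for key in ("cohort_path", "cost_schedule_path", "out_dir", "master_seed",
                    "p_zero_true", "verbosity"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def echo(self) -> dict:
        d = {
            "cohort_path": self.cohort_path,
            "out_dir": self.out_dir,
            "master_seed": self.master_seed,
            "p_zero_true": self.p_zero_true,
            "rounding": dataclasses.asdict(self.rule),
            "simulation": dataclasses.asdict(self.sim),
            "stratification": dataclasses.asdict(self.plan),
            "cost_schedule_path": self.cost_schedule_path,
        }
        if self.generator is not None:
            g = dataclasses.asdict(self.generator)
            g["age_by_sex"] = {k: list(v) for k, v in g["age_by_sex"].items()}
            d["generator"] = g
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except BProundError:
                raise
            except Exception as err:  # pragma: no cover - defensive context wrap
                raise BProundError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


def run_full_analysis(config: RunConfig) -> Path:
    """Execute every analysis stage and write all artifacts to the run
    directory, which is returned."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO if config.verbosity else logging.WARNING)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.echo(), fh, sort_keys=False)

    if config.generator is not None:
        cohort = _stage("generate_cohort")(generate_cohort)(config.generator)
        write_cohort(cohort, out / "cohort.csv", seed=config.generator.seed)
    else:
        cohort, violations = validate_cohort_file(config.cohort_path)
        if violations:
            raise SchemaError(
                "cohort file failed validation:\n" + "\n".join(violations)
            )

    # digit audit
    dist = _stage("digit_audit")(digit_distribution)(cohort)
    decomposition = estimate_rounded_fraction(dist[0], config.p_zero_true)
    pd.Series(dist, name="proportion").rename_axis("digit").to_csv(out / "digit_distribution.csv")

    # per-sex rounding experiment
    experiment = RoundingExperiment(cohort, config.rule, config.sim)
    results = _stage("rounding_experiment")(experiment.fit)()
    for sex, fit in results.model1_fits.items():
        fit.to_yaml(out / f"model1_{sex}.yaml")

    # convergence diagnostic from the realized simulations
    convergence = None
    if results.results:
        first = next(iter(results.results.values()))
        grid = [g for g in config.sim.convergence_grid if g <= config.sim.n_simulations]
        if not grid:
            grid = [config.sim.n_simulations]
        convergence = convergence_table(first, grid)

    # whole-cohort generalization
    generalized = None
    if results.results and decomposition.rounded_fraction_estimate >= 0:
        sizes = {
            sex: int(((cohort["sex"] == sex) & (cohort["prior_cvd"] == 0)).sum())
            for sex in results.results
        }
        generalized = _stage("generalization")(generalize_to_cohort)(
            results.results, decomposition, sizes
        )

    # cost of misclassification at the subset (upper-bound) level
    schedule = (
        CostSchedule.from_yaml(config.cost_schedule_path)
        if config.cost_schedule_path
        else CostSchedule.default()
    )
    over_total = sum(r.overtreated_to_moderate for r in results.results.values())
    under_total = sum(r.undertreated for r in results.results.values())
    cost_summary = _stage("cost_model")(misclassification_cost)(
        over_total, under_total, schedule
    )

    _stage("report")(summarize_report)(
        results.results,
        out,
        comparisons=results.comparisons,
        convergence=convergence,
        generalized=generalized,
        cost_summary=cost_summary,
    )
    logger.info("run complete: %s", out)
    return out


_BINARY_COLUMNS = [
    "ex_smoker", "current_smoker", "family_history", "atrial_fibrillation",
    "diabetes", "bp_med", "lipid_med", "antithrombotic_med", "event", "prior_cvd",
]


def validate_cohort_file(path) -> tuple[pd.DataFrame | None, list[str]]:
    """Validate a delimited cohort file against the cohort schema.

    Returns ``(cohort, violations)``: the parsed table (None when column-level
    problems make it unusable) and a line-referenced list of violations.
    Line numbers refer to data rows (header = line 1).
    """
    df = read_cohort(path)
    if len(df) == 0:
        raise EmptyInputError(f"cohort file {path} has no records")
    violations: list[str] = []
    required = [c for c in COHORT_COLUMNS if c not in ("age_c", "sbp_c", "tchdl_c")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return None, [f"missing column(s): {', '.join(missing)}"]

    def _lineno(idx) -> int:
        return int(idx) + 2  # header line + 1-based

    sbp_num = pd.to_numeric(df["sbp"], errors="coerce")
    for idx in df.index[sbp_num.isna() | (sbp_num != sbp_num.round()) | (sbp_num <= 0)]:
        violations.append(f"line {_lineno(idx)}: column 'sbp' must be a positive integer "
                          f"(got {df.at[idx, 'sbp']!r})")
    for idx in df.index[pd.to_numeric(df["time"], errors="coerce").fillna(-1) <= 0]:
        violations.append(f"line {_lineno(idx)}: column 'time' must be > 0")
    for idx in df.index[~df["sex"].isin(["M", "F"])]:
        violations.append(f"line {_lineno(idx)}: column 'sex' must be M or F")
    for idx in df.index[~df["ethnicity"].isin(ETHNICITY_LEVELS)]:
        violations.append(f"line {_lineno(idx)}: invalid ethnicity {df.at[idx, 'ethnicity']!r}")
    for idx in df.index[~df["bmi_class"].isin(BMI_LEVELS)]:
        violations.append(f"line {_lineno(idx)}: invalid bmi_class {df.at[idx, 'bmi_class']!r}")
    for idx in df.index[~df["nzdep"].isin([1, 2, 3, 4, 5])]:
        violations.append(f"line {_lineno(idx)}: nzdep must be 1..5")
    for col in _BINARY_COLUMNS:
        bad = df.index[~df[col].isin([0, 1])]
        for idx in bad:
            violations.append(f"line {_lineno(idx)}: column {col!r} must be 0 or 1")
    both = df.index[(df["ex_smoker"] == 1) & (df["current_smoker"] == 1)]
    for idx in both:
        violations.append(f"line {_lineno(idx)}: ex_smoker and current_smoker cannot both be 1")
    if violations:
        return None, violations

    out = df.copy()
    for raw, centred in (("age", "age_c"), ("sbp", "sbp_c"), ("tchdl", "tchdl_c")):
        if centred not in out.columns:
            out[centred] = out[raw] - out[raw].mean()
    return out, []
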