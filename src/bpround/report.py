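"""Report rendering: confusion-matrix tables, misclassification-rate and
hazard-ratio difference plots, convergence plot, and the cost summary.

All numeric tables are written both as plain text (the report) and as
delimited files; figures are PNG.  Output is deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .cox import ModelComparison
from .errors import BProundError
from .experiment import CATEGORY_LABELS, GeneralizedCounts, MisclassificationResult

__all__ = ["summarize_report"]


def _matrix_csv(res: MisclassificationResult) -> pd.DataFrame:
    rows = []
    for i, orig in enumerate(CATEGORY_LABELS):
        for j, new in enumerate(CATEGORY_LABELS):
            rows.append(
                {
                    "original": orig,
                    "rounded": new,
                    "mean_count": res.mean_matrix[i, j],
                    "ci_lower": res.ci_lower[i, j],
                    "ci_upper": res.ci_upper[i, j],
                    "row_percent": res.row_percentages[i, j],
                }
            )
    return pd.DataFrame(rows)


def _rate_plot(results: dict[str, MisclassificationResult], path: Path) -> None:
    fig, axes = plt.subplots(1, max(len(results), 1), figsize=(5 * max(len(results), 1), 4),
                             squeeze=False)
    for ax, (sex, res) in zip(axes[0], results.items()):
        pct = res.row_percentages
        labels, values = [], []
        for i, orig in enumerate(CATEGORY_LABELS):
            for j, new in enumerate(CATEGORY_LABELS):
                if i != j:
                    labels.append(f"{orig}→{new}")
                    values.append(pct[i, j])
        ax.bar(range(len(values)), values, color="steelblue")
        ax.set_xticks(range(len(labels)))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=8)
        ax.set_ylabel("% of original category")
        ax.set_title(f"Misclassification rates, sex={sex}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _hr_plot(comparisons: dict[str, ModelComparison], path: Path) -> None:
    fig, axes = plt.subplots(1, max(len(comparisons), 1),
                             figsize=(6 * max(len(comparisons), 1), 4), squeeze=False)
    for ax, (sex, comp) in zip(axes[0], comparisons.items()):
        rel = comp.table["relative_difference_percent"]
        ax.barh(range(len(rel)), rel.to_numpy(), color="darkorange")
        ax.set_yticks(range(len(rel)))
        ax.set_yticklabels(rel.index, fontsize=7)
        ax.set_xlabel("relative HR difference (%)")
        ax.set_title(f"Model 2 vs Model 1 hazard ratios, sex={sex}")
        ax.axvline(0, color="k", lw=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _convergence_plot(table: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["n_simulations"], table["percent_correct"], "o-", color="seagreen")
    ax.fill_between(table["n_simulations"], table["ci_lower"], table["ci_upper"],
                    alpha=0.3, color="seagreen")
    ax.set_xscale("log")
    ax.set_xlabel("number of simulations")
    ax.set_ylabel("% correctly classified")
    ax.set_title("Classification accuracy by simulation count")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_report(
    results: dict[str, MisclassificationResult],
    out_dir,
    comparisons: dict[str, ModelComparison] | None = None,
    convergence: pd.DataFrame | None = None,
    generalized: GeneralizedCounts | None = None,
    cost_summary: dict | None = None,
) -> Path:
    """Render all result artifacts into ``out_dir``; returns the report path.

    An empty ``results`` mapping produces an empty report with a warning.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise BProundError(f"cannot create report directory {out}: {err}") from err

    lines: list[str] = ["Zero end-digit SBP rounding: misclassification report", ""]
    if not results:
        warnings.warn("no misclassification results to report; writing empty report",
                      stacklevel=2)
        lines.append("(no results)")
    undertreated = 0.0
    over_moderate = 0.0
    for sex, res in results.items():
        _matrix_csv(res).to_csv(out / f"misclassification_{sex}.csv", index=False)
        lines.append(res.summary())
        lines.append("")
        undertreated += res.undertreated
        over_moderate += res.overtreated_to_moderate
    if results:
        lines.append(f"Total undertreated (moderate->low), all sexes: {undertreated:.0f}")
        lines.append(f"Total overclassified into moderate (low->moderate), all sexes: "
                     f"{over_moderate:.0f}")
        lines.append("")
        _rate_plot(results, out / "misclassification_rates.png")
    if comparisons:
        _hr_plot(comparisons, out / "hazard_ratio_differences.png")
        for sex, comp in comparisons.items():
            comp.table.to_csv(out / f"hr_comparison_{sex}.csv")
            lines.append(
                f"Hazard-ratio comparison ({sex}): max |relative difference| = "
                f"{comp.max_abs_relative_difference_percent:.3f}%, paired t p = {comp.p_value:.3f}"
            )
        lines.append("")
    if convergence is not None:
        convergence.to_csv(out / "convergence.csv", index=False)
        _convergence_plot(convergence, out / "convergence.png")
    if generalized is not None:
        lines.append("Whole-cohort generalization (scaled counts):")
        for sex, d in generalized.per_sex.items():
            lines.append(
                f"  {sex}: undertreated {d['undertreated']}, "
                f"overtreated->moderate {d['overtreated_to_moderate']}, "
                f"overtreated->high {d['overtreated_to_high']} "
                f"(scaling factor {generalized.scaling_factors[sex]:.4f})"
            )
        lines.append(f"  totals: undertreated {generalized.undertreated_total}, "
                     f"overtreated {generalized.overtreated_total}")
        lines.append("")
    if cost_summary is not None:
        lines.append("Cost of misclassification (NZD):")
        lines.append(
            f"  overtreatment into moderate: {cost_summary['overtreated_to_moderate']:.1f} "
            f"people x {cost_summary['incremental_cost_per_person_mid']:.2f} = "
            f"{cost_summary['overtreatment_cost_mid']:.2f} "
            f"(max-tier bound {cost_summary['overtreatment_cost_max']:.2f})"
        )
        band = cost_summary["undertreatment_scenario_band"]
        lines.append(
            f"  undertreated: {cost_summary['undertreated']:.1f} people; avoidable inpatient "
            f"cost scenario band {band[0]:.2f}-{band[1]:.2f} "
            f"({cost_summary['inpatient_cost_per_patient_range'][0]:.0f}-"
            f"{cost_summary['inpatient_cost_per_patient_range'][1]:.0f} per patient)"
        )
        lines.append("")
    report_path = out / "report.txt"
    try:
        report_path.write_text("\n".join(lines))
    except OSError as err:
        raise BProundError(f"cannot write report to {report_path}: {err}") from err
    return report_path
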