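"""Misclassification experiment: categories, conservation, convergence,
whole-cohort generalization, reporting."""

import numpy as np
import pandas as pd
import pytest

from bpround import (
    GeneratorConfig,
    RoundingRule,
    SimulationConfig,
    categorize,
    estimate_rounded_fraction,
    generalize_to_cohort,
    generate_cohort,
    run_rounding_experiment,
    summarize_report,
)
from bpround.digits import IDENTITY_RULE
from bpround.errors import InputError, UndefinedScalingError
from bpround.experiment import MisclassificationResult, convergence_table

pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


@pytest.fixture(scope="module")
def experiment_cohort():
    return generate_cohort(GeneratorConfig(n_people=5000, seed=17))


@pytest.fixture(scope="module")
def default_results(experiment_cohort):
    return run_rounding_experiment(
        experiment_cohort, RoundingRule(rng_seed=5), SimulationConfig(n_simulations=30, rng_seed=9)
    )


@pytest.mark.parametrize(
    "risk, label",
    [(0.0, "low"), (4.99, "low"), (5.0, "moderate"), (15.0, "moderate"),
     (15.01, "high"), (100.0, "high")],
)
def test_category_boundaries(risk, label):
    assert categorize(risk) == label


@pytest.mark.parametrize("bad", [-0.1, 100.1, float("nan")])
def test_category_out_of_range(bad):
    with pytest.raises(InputError):
        categorize(bad)


def test_identity_rule_gives_exactly_diagonal_matrix(experiment_cohort):
    res = run_rounding_experiment(
        experiment_cohort, IDENTITY_RULE, SimulationConfig(n_simulations=3, rng_seed=1)
    )
    for sex, r in res.results.items():
        off = r.mean_matrix - np.diag(np.diag(r.mean_matrix))
        assert (off == 0).all()
        np.testing.assert_array_equal(np.diag(r.mean_matrix), r.original_counts)
        np.testing.assert_array_equal(r.ci_lower, r.mean_matrix)
        np.testing.assert_array_equal(r.ci_upper, r.mean_matrix)
        assert (r.percent_correct_per_sim == 100.0).all()


def test_every_simulation_conserves_row_totals(default_results):
    for r in default_results.results.values():
        row_sums = r.sim_matrices.sum(axis=2)
        np.testing.assert_array_equal(row_sums, np.broadcast_to(r.original_counts, row_sums.shape))
        np.testing.assert_allclose(r.mean_matrix.sum(axis=1), r.original_counts)


def test_corner_cells_are_zero(default_results):
    """A <=5 mmHg SBP perturbation cannot carry anyone across two category
    boundaries at once."""
    for r in default_results.results.values():
        assert (r.sim_matrices[:, 0, 2] == 0).all()
        assert (r.sim_matrices[:, 2, 0] == 0).all()


def test_adjacent_under_and_over_flows_same_order(default_results):
    """Symmetric rounding with a positive SBP effect moves comparable counts
    down and up between adjacent categories."""
    for r in default_results.results.values():
        under = r.undertreated
        over = r.overtreated_to_moderate
        assert under > 0 and over > 0
        assert 1 / 3 <= under / over <= 3


def test_fixed_seed_reproducible(experiment_cohort):
    kwargs = dict(rule=RoundingRule(rng_seed=5), sim=SimulationConfig(n_simulations=5, rng_seed=9))
    a = run_rounding_experiment(experiment_cohort, **kwargs)
    b = run_rounding_experiment(experiment_cohort, **kwargs)
    for sex in a.results:
        np.testing.assert_array_equal(a[sex].sim_matrices, b[sex].sim_matrices)
        np.testing.assert_array_equal(a[sex].mean_matrix, b[sex].mean_matrix)


def test_attenuated_rounding_reduces_off_diagonal_mass(experiment_cohort):
    """Scaling every rounding displacement toward zero weakly decreases the
    misclassified mass (no-refit mode isolates the perturbation)."""
    sim = SimulationConfig(n_simulations=10, rng_seed=3, refit_per_simulation=False)
    full = run_rounding_experiment(experiment_cohort, RoundingRule(rng_seed=5), sim)
    half = run_rounding_experiment(
        experiment_cohort, RoundingRule(rng_seed=5, delta_scale=0.5), sim
    )
    for sex in full.results:
        off_full = full[sex].sim_matrices.sum(axis=(1, 2)) - full[sex].sim_matrices[:, [0, 1, 2], [0, 1, 2]].sum(axis=1)
        off_half = half[sex].sim_matrices.sum(axis=(1, 2)) - half[sex].sim_matrices[:, [0, 1, 2], [0, 1, 2]].sum(axis=1)
        assert off_half.mean() <= off_full.mean()


def test_model_comparison_small_relative_difference(default_results):
    """Rounding barely moves the hazard ratios (mirrors the flat HR pattern
    of the motivating analysis)."""
    for comp in default_results.comparisons.values():
        assert comp.max_abs_relative_difference_percent < 10.0
        assert 0.0 <= comp.p_value <= 1.0


def test_convergence_ci_width_shrinks(default_results):
    first = next(iter(default_results.results.values()))
    table = convergence_table(first, [5, 30])
    assert table.loc[1, "ci_width"] < table.loc[0, "ci_width"]
    assert (table["ci_lower"] <= table["percent_correct"]).all()
    assert (table["percent_correct"] <= table["ci_upper"]).all()


def test_convergence_empty_grid_rejected(default_results):
    with pytest.raises(InputError):
        convergence_table(next(iter(default_results.results.values())), [])


def _fake_result(sex, matrix):
    m = np.asarray(matrix, dtype=float)
    return MisclassificationResult(
        sex=sex, mean_matrix=m, ci_lower=m, ci_upper=m, n_simulations=1, n_dropped=0,
        original_counts=m.sum(axis=1).astype(int), sim_matrices=m[None].astype(np.int64),
        n_subjects=int(m.sum()), n_rounded=int(m.sum()),
    )


WOMEN_T4 = [[105_629, 654, 0], [670, 20_196, 43], [0, 45, 1357]]
MEN_T4 = [[112_257, 1354, 0], [1291, 43_839, 215], [0, 194, 4378]]


def test_generalize_scaling_arithmetic():
    results = {"F": _fake_result("F", WOMEN_T4), "M": _fake_result("M", MEN_T4)}
    dec = estimate_rounded_fraction(0.32, 0.20)
    # explicit factor 1: outputs equal inputs
    same = generalize_to_cohort(results, dec, {"F": 1, "M": 1}, scaling_factor=1.0)
    assert same.per_sex["F"]["undertreated"] == 670
    assert same.undertreated_total == 1961
    # the 304-from-1961 ratio arithmetic under an explicit factor
    scaled = generalize_to_cohort(results, dec, {"F": 1, "M": 1}, scaling_factor=0.155)
    assert scaled.undertreated_total == 304
    # zero factor: all zero, with a warning
    with pytest.warns(UserWarning):
        zero = generalize_to_cohort(results, dec, {"F": 1, "M": 1}, scaling_factor=0.0)
    assert zero.undertreated_total == 0


def test_generalize_default_factor_is_cohort_ratio():
    res = {"F": _fake_result("F", WOMEN_T4)}
    dec = estimate_rounded_fraction(0.32, 0.20)
    n_f = int(np.asarray(WOMEN_T4).sum())
    out = generalize_to_cohort(res, dec, {"F": 2 * n_f})
    # experiment rounded n_f of 2*n_f people -> factor = 0.12 / 0.5
    assert out.scaling_factors["F"] == pytest.approx(0.12 / 0.5)


def test_generalize_without_rounded_records_is_undefined():
    res = {"F": _fake_result("F", WOMEN_T4)}
    res["F"].n_rounded = 0
    dec = estimate_rounded_fraction(0.32, 0.20)
    with pytest.raises(UndefinedScalingError):
        generalize_to_cohort(res, dec, {"F": 100})


def test_report_aggregates_published_layout(tmp_path):
    """Fed the printed per-sex matrices, the report totals 1961 undertreated
    and 2008 overclassified into moderate."""
    results = {"F": _fake_result("F", WOMEN_T4), "M": _fake_result("M", MEN_T4)}
    path = summarize_report(results, tmp_path)
    text = path.read_text()
    assert "1961" in text
    assert "2008" in text
    assert (tmp_path / "misclassification_F.csv").exists()
    assert (tmp_path / "misclassification_rates.png").exists()


def test_report_empty_results_warns(tmp_path):
    with pytest.warns(UserWarning):
        path = summarize_report({}, tmp_path / "empty")
    assert "(no results)" in path.read_text()
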