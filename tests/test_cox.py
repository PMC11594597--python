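"""Cox engine: partial-likelihood oracle, baseline survival, risk formula."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from bpround import CoxRiskModel, GeneratorConfig, compare_models, fit_cox, generate_cohort
from bpround.cox import CoxRiskResults
from bpround.errors import DegenerateFitError, FitError, SchemaError

ZERO_BETAS = {k: 0.0 for k in GeneratorConfig().true_betas}


def _partial_likelihood_neg_log(beta, times, events, x):
    """Explicit Cox partial likelihood for distinct event times."""
    order = np.argsort(times)
    t, e, xv = times[order], events[order], x[order]
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk_set = xv[i:]
            ll += beta * xv[i] - np.log(np.sum(np.exp(beta * risk_set)))
    return -ll


@pytest.mark.parametrize(
    "x, times, events",
    [
        (np.array([1.0, 0, 1, 0, 1, 0]), np.array([1.0, 2, 3, 4, 5, 6]),
         np.array([1, 1, 0, 1, 1, 0])),
        (np.array([0.3, -1.2, 0.8, 2.1, -0.4, 0.0, 1.5, -0.9]),
         np.array([2.0, 1, 5, 3, 8, 4, 7, 6]),
         np.array([1, 1, 1, 0, 1, 1, 0, 1])),
    ],
)
def test_fit_matches_brute_force_partial_likelihood(x, times, events):
    """On tiny cohorts with distinct times the fitted coefficient maximises
    the hand-written partial likelihood to 1e-4."""
    df = pd.DataFrame({"x": x, "time": times, "event": events})
    fit = CoxRiskModel(df, covariates=["x"]).fit()
    oracle = minimize_scalar(
        _partial_likelihood_neg_log, bounds=(-5, 5), method="bounded",
        args=(times, events, x), options={"xatol": 1e-10},
    )
    assert fit.betas["x"] == pytest.approx(oracle.x, abs=1e-4)


def test_monotone_likelihood_guard_triggers():
    """Perfect separation (the exposed subject always fails first) has an
    unbounded partial likelihood and must raise rather than return."""
    df = pd.DataFrame(
        {"x": [1.0, 1.0, 0.0, 0.0], "time": [1.0, 2.0, 3.0, 4.0], "event": [1, 1, 1, 1]}
    )
    with pytest.raises(FitError):
        CoxRiskModel(df, covariates=["x"]).fit()


def test_no_events_is_degenerate():
    df = pd.DataFrame({"x": [0.1, 0.2], "time": [1.0, 2.0], "event": [0, 0]})
    with pytest.raises(DegenerateFitError):
        CoxRiskModel(df, covariates=["x"]).fit()


def test_null_baseline_survival_matches_exponential():
    """With all true betas zero, the Breslow baseline survival at 5 years
    estimates e^(-5h)."""
    h = 0.03
    cohort = generate_cohort(
        GeneratorConfig(n_people=10_000, true_betas=ZERO_BETAS,
                        baseline_hazard_rate=h, seed=41)
    )
    fit = fit_cox(cohort)
    expected = np.exp(-5 * h)
    # SE of the cumulative hazard ~ sqrt(events)/at-risk; 0.015 covers 3 SD here
    assert fit.s0_5y == pytest.approx(expected, abs=0.015)


def _manual_results(betas, s0):
    names = list(betas)
    return CoxRiskResults(
        betas=pd.Series(betas),
        standard_errors=pd.Series({k: 0.1 for k in names}),
        s0_5y=s0,
        centring_means={},
        horizon=5.0,
        fit_meta={"n": 0, "events": 0, "converged": True, "ties": "efron"},
    )


@pytest.mark.parametrize(
    "s0, x, expected",
    [
        (0.95, 0.0, 5.0),                     # lp = 0
        (0.95, np.log(2.0), 9.75),            # 1 - 0.95^2
        (1.0, 3.0, 0.0),                      # no baseline hazard
    ],
)
def test_risk_formula_closed_forms(s0, x, expected):
    fit = _manual_results({"x": 1.0}, s0)
    df = pd.DataFrame({"x": [x]})
    assert fit.predict_risk(df)["risk_percent"].iloc[0] == pytest.approx(expected, abs=1e-9)


def test_risk_increasing_in_linear_predictor():
    fit = _manual_results({"x": 1.0}, 0.95)
    lp = np.linspace(-3, 3, 50)
    risks = fit.predict_risk(pd.DataFrame({"x": lp}))["risk_percent"].to_numpy()
    assert (np.diff(risks) > 0).all()


def test_predict_missing_covariate_names_it(small_cohort):
    fit = fit_cox(small_cohort[small_cohort["sex"] == "M"])
    with pytest.raises(SchemaError, match="tchdl"):
        fit.predict_risk(small_cohort.drop(columns=["tchdl"]))


def test_covariate_shift_changes_baseline_not_risks():
    """Adding a constant to a covariate is absorbed: s0 changes, risks don't."""
    rng = np.random.default_rng(7)
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(1 / (0.1 * np.exp(0.5 * x)))
    df = pd.DataFrame({"x": x, "time": np.minimum(t, 5.0), "event": (t <= 5.0).astype(int)})
    fit1 = CoxRiskModel(df, covariates=["x"]).fit()
    shifted = df.assign(x=df["x"] + 2.0)
    fit2 = CoxRiskModel(shifted, covariates=["x"]).fit()
    assert fit1.betas["x"] == pytest.approx(fit2.betas["x"], abs=1e-6)
    assert fit1.s0_5y != pytest.approx(fit2.s0_5y, abs=1e-4)
    r1 = fit1.predict_risk(df)["risk_percent"].to_numpy()
    r2 = fit2.predict_risk(shifted)["risk_percent"].to_numpy()
    np.testing.assert_allclose(r1, r2, atol=1e-8)


def test_compare_models_identity_is_degenerate(small_cohort):
    fit = fit_cox(small_cohort[small_cohort["sex"] == "F"])
    comp = compare_models(fit, fit)
    assert comp.degenerate
    assert comp.p_value == 1.0
    assert comp.max_abs_relative_difference_percent == 0.0
    assert (comp.table["relative_difference_percent"] == 0).all()


def test_compare_models_relative_difference_arithmetic():
    fit1 = _manual_results({"a": np.log(2.0), "b": 0.1}, 0.95)
    fit2 = _manual_results({"a": np.log(2.01), "b": 0.1}, 0.95)
    comp = compare_models(fit1, fit2)
    assert comp.table.loc["a", "relative_difference_percent"] == pytest.approx(0.5)
    assert comp.max_abs_relative_difference_percent == pytest.approx(0.5)


def test_compare_models_mismatched_covariates():
    fit1 = _manual_results({"a": 0.1}, 0.95)
    fit2 = _manual_results({"b": 0.1}, 0.95)
    with pytest.raises(SchemaError):
        compare_models(fit1, fit2)


def test_results_yaml_roundtrip(small_cohort, tmp_path):
    fit = fit_cox(small_cohort[small_cohort["sex"] == "M"])
    path = tmp_path / "fit.yaml"
    fit.to_yaml(path)
    back = CoxRiskResults.from_yaml(path)
    pd.testing.assert_series_equal(back.betas, fit.betas, check_names=False)
    assert back.s0_5y == fit.s0_5y
    r1 = fit.predict_risk(small_cohort)["risk_percent"]
    r2 = back.predict_risk(small_cohort)["risk_percent"]
    np.testing.assert_allclose(r1, r2)
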