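"""Design-matrix construction shared by the cohort generator and the Cox engine.

The covariate set is the standard primary-prevention CVD risk-factor panel used
by the New Zealand 5-year risk equation family: centred age, SBP and TC:HDL
ratio, ethnicity and deprivation-quintile indicator blocks, smoking status,
family history, atrial fibrillation, diabetes, BMI-class indicators and three
baseline medication flags.  Reference levels: European ethnicity, NZDep
quintile 1, normal BMI.
"""

from __future__ import annotations

import pandas as pd

from .errors import SchemaError

ETHNICITY_LEVELS = ["European", "Maori", "Pacific", "Indian", "Chinese/other Asian"]
BMI_LEVELS = [
    "normal",
    "underweight",
    "overweight",
    "obesity class 1",
    "obesity class 2",
    "obesity class 3",
    "bmi unknown",
]
NZDEP_LEVELS = [1, 2, 3, 4, 5]

# design-column name -> (source column, level) for indicator blocks
_ETH_COLS = {
    "eth_maori": "Maori",
    "eth_pacific": "Pacific",
    "eth_indian": "Indian",
    "eth_asian": "Chinese/other Asian",
}
_BMI_COLS = {
    "bmi_underweight": "underweight",
    "bmi_overweight": "overweight",
    "bmi_obesity1": "obesity class 1",
    "bmi_obesity2": "obesity class 2",
    "bmi_obesity3": "obesity class 3",
    "bmi_unknown": "bmi unknown",
}

#: continuous raw column -> centred design column
CONTINUOUS_COLS = {"age": "age_c", "sbp": "sbp_c", "tchdl": "tchdl_c"}

BINARY_COLS = [
    "ex_smoker",
    "current_smoker",
    "family_history",
    "atrial_fibrillation",
    "diabetes",
    "bp_med",
    "lipid_med",
    "antithrombotic_med",
]

#: canonical ordering of the full design matrix
DESIGN_COLUMNS = (
    ["age_c"]
    + list(_ETH_COLS)
    + [f"nzdep_{q}" for q in (2, 3, 4, 5)]
    + BINARY_COLS[:5]
    + ["sbp_c", "tchdl_c"]
    + list(_BMI_COLS)
    + BINARY_COLS[5:]
)

REQUIRED_RAW_COLUMNS = (
    ["age", "ethnicity", "nzdep"] + BINARY_COLS[:5] + ["sbp", "tchdl", "bmi_class"] + BINARY_COLS[5:]
)


def build_design_matrix(
    df: pd.DataFrame,
    centring_means: dict[str, float] | None = None,
    sbp_column: str = "sbp",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Expand raw covariates into the reference-coded design matrix.

    Continuous covariates (age, SBP, TC:HDL) are mean-centred; if
    ``centring_means`` is given those means are used (prediction mode),
    otherwise the sample means of ``df`` are computed and returned
    (fitting mode).  ``sbp_column`` selects which SBP recording feeds the
    linear predictor (e.g. a latent or a rounded copy).

    Returns ``(X, means)`` with ``X`` ordered per :data:`DESIGN_COLUMNS`.
    """
    missing = [c for c in REQUIRED_RAW_COLUMNS if c != "sbp" and c not in df.columns]
    if sbp_column not in df.columns:
        missing.append(sbp_column)
    if missing:
        raise SchemaError(f"cohort is missing required column(s): {', '.join(missing)}")

    if centring_means is None:
        means = {
            "age": float(df["age"].mean()),
            "sbp": float(df[sbp_column].mean()),
            "tchdl": float(df["tchdl"].mean()),
        }
    else:
        means = dict(centring_means)

    X = pd.DataFrame(index=df.index)
    X["age_c"] = df["age"].astype(float) - means["age"]
    for col, level in _ETH_COLS.items():
        X[col] = (df["ethnicity"] == level).astype(float)
    for q in (2, 3, 4, 5):
        X[f"nzdep_{q}"] = (df["nzdep"].astype(int) == q).astype(float)
    for col in BINARY_COLS[:5]:
        X[col] = df[col].astype(float)
    X["sbp_c"] = df[sbp_column].astype(float) - means["sbp"]
    X["tchdl_c"] = df["tchdl"].astype(float) - means["tchdl"]
    for col, level in _BMI_COLS.items():
        X[col] = (df["bmi_class"] == level).astype(float)
    for col in BINARY_COLS[5:]:
        X[col] = df[col].astype(float)
    return X[DESIGN_COLUMNS], means
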