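"""Covariate designs shared by the simulator and the two regression models.

Two designs are defined here so that the generator, the estimators and the
marginal-effect machinery agree exactly on column order:

* the *encounter design* — intercept, lagged log clinical measures, log age,
  a male indicator, clinical-cluster dummies, insurance dummies, and six
  ZIP-code (community) covariates — used by the zero-inflated Poisson and
  zero-truncated Poisson encounter models;
* the *transition design* — intercept, the two encounter counts, log age,
  five community covariates, and the twelve encounter x covariate products —
  used by the 9-category multinomial transition model.

Percentages enter as proportions in [0, 1]; income, population, age, glucose
and cholesterol enter through natural logs where the design says so.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_INSURANCE_GROUPS = 13
N_CLINICAL_CLUSTERS = 4

#: patient-level slopes of the encounter model, in design order (after const)
ENCOUNTER_PATIENT_TERMS = [
    "log_cholesterol_lag",
    "log_glucose_lag",
    "log_age",
    "male",
]
#: community (ZIP-code) slopes of the encounter model, in design order
ENCOUNTER_COMMUNITY_TERMS = [
    "log_population",
    "pct_white",
    "pct_black",
    "log_income",
    "pct_highschool",
    "pct_college",
]

CLUSTER_DUMMY_TERMS = [f"cluster_{j}" for j in range(2, N_CLINICAL_CLUSTERS + 1)]
INSURANCE_DUMMY_TERMS = [f"insurance_{k}" for k in range(2, N_INSURANCE_GROUPS + 1)]

#: full encounter-model column order (reference levels: cluster 1, insurance 1,
#: gender female)
ENCOUNTER_DESIGN_COLUMNS = (
    ["const"]
    + ENCOUNTER_PATIENT_TERMS
    + CLUSTER_DUMMY_TERMS
    + INSURANCE_DUMMY_TERMS
    + ENCOUNTER_COMMUNITY_TERMS
)

#: sociodemographic covariates that interact with encounters in the
#: transition model, in printed order
TRANSITION_MODIFIERS = [
    "log_age",
    "pct_white",
    "pct_black",
    "log_income",
    "pct_highschool",
    "pct_college",
]

TRANSITION_MAIN_TERMS = ["phys_encounters", "tel_encounters"] + TRANSITION_MODIFIERS

TRANSITION_DESIGN_COLUMNS = (
    ["const"]
    + TRANSITION_MAIN_TERMS
    + [f"phys_x_{m}" for m in TRANSITION_MODIFIERS]
    + [f"tel_x_{m}" for m in TRANSITION_MODIFIERS]
)

#: glucose states ordered by severity
STATES = ["N", "P", "D"]

#: the nine transition types; D->D first because it is the reference category
TRANSITION_TYPES = [
    "D->D",
    "D->N",
    "D->P",
    "N->D",
    "N->N",
    "N->P",
    "P->D",
    "P->N",
    "P->P",
]
REFERENCE_TRANSITION = "D->D"
NONREF_TRANSITIONS = TRANSITION_TYPES[1:]

N_TRANSITION_COEF = len(TRANSITION_DESIGN_COLUMNS)  # 21 per non-reference category


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"{what} requires columns {missing}")


def encounter_design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Expand a prepared panel into the encounter-model design matrix.

    Expects natural-scale columns ``cholesterol_lag``, ``glucose_lag``,
    ``age``, ``male`` (0/1), ``clinical_cluster`` (1..4), ``insurance``
    (1..13), ``population``, ``income`` and the four community proportions.
    """
    _require_columns(
        df,
        ["cholesterol_lag", "glucose_lag", "age", "male", "clinical_cluster",
         "insurance", "population", "income", "pct_white", "pct_black",
         "pct_highschool", "pct_college"],
        "encounter design",
    )
    out = pd.DataFrame(index=df.index)
    out["const"] = 1.0
    out["log_cholesterol_lag"] = np.log(df["cholesterol_lag"].to_numpy(float))
    out["log_glucose_lag"] = np.log(df["glucose_lag"].to_numpy(float))
    out["log_age"] = np.log(df["age"].to_numpy(float))
    out["male"] = df["male"].to_numpy(float)
    cluster = df["clinical_cluster"].to_numpy(int)
    for j in range(2, N_CLINICAL_CLUSTERS + 1):
        out[f"cluster_{j}"] = (cluster == j).astype(float)
    ins = df["insurance"].to_numpy(int)
    for k in range(2, N_INSURANCE_GROUPS + 1):
        out[f"insurance_{k}"] = (ins == k).astype(float)
    out["log_population"] = np.log(df["population"].to_numpy(float))
    out["pct_white"] = df["pct_white"].to_numpy(float)
    out["pct_black"] = df["pct_black"].to_numpy(float)
    out["log_income"] = np.log(df["income"].to_numpy(float))
    out["pct_highschool"] = df["pct_highschool"].to_numpy(float)
    out["pct_college"] = df["pct_college"].to_numpy(float)
    return out[ENCOUNTER_DESIGN_COLUMNS]


def transition_natural_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Pull the eight natural-scale transition covariates out of a frame.

    Accepts either already-logged columns (``log_age`` / ``log_income``) or
    the raw ``age`` / ``income`` columns, which are logged here.
    """
    out = pd.DataFrame(index=df.index)
    out["phys_encounters"] = df["phys_encounters"].to_numpy(float)
    out["tel_encounters"] = df["tel_encounters"].to_numpy(float)
    out["log_age"] = (
        df["log_age"].to_numpy(float)
        if "log_age" in df
        else np.log(df["age"].to_numpy(float))
    )
    for c in ["pct_white", "pct_black"]:
        out[c] = df[c].to_numpy(float)
    out["log_income"] = (
        df["log_income"].to_numpy(float)
        if "log_income" in df
        else np.log(df["income"].to_numpy(float))
    )
    out["pct_highschool"] = df["pct_highschool"].to_numpy(float)
    out["pct_college"] = df["pct_college"].to_numpy(float)
    return out


def expand_transition_design(natural: pd.DataFrame) -> pd.DataFrame:
    """Expand the eight natural covariates into the 21-column design
    (intercept, main effects, encounter x modifier products)."""
    _require_columns(natural, TRANSITION_MAIN_TERMS, "transition design")
    out = pd.DataFrame(index=natural.index)
    out["const"] = 1.0
    for c in TRANSITION_MAIN_TERMS:
        out[c] = natural[c].to_numpy(float)
    phys = natural["phys_encounters"].to_numpy(float)
    tel = natural["tel_encounters"].to_numpy(float)
    for m in TRANSITION_MODIFIERS:
        v = natural[m].to_numpy(float)
        out[f"phys_x_{m}"] = phys * v
        out[f"tel_x_{m}"] = tel * v
    return out[TRANSITION_DESIGN_COLUMNS]


def transition_design_gradient(natural: pd.DataFrame, variable: str) -> np.ndarray:
    """d(design row)/d(variable) for every observation: an (n, 21) array.

    ``variable`` is one of the eight natural covariates. The derivative runs
    through the interaction products (d(phys * m)/d(phys) = m, and
    d(phys * m)/d(m) = phys).
    """
    if variable not in TRANSITION_MAIN_TERMS:
        raise KeyError(
            f"{variable!r} is not a transition-model covariate "
            f"(expected one of {TRANSITION_MAIN_TERMS})"
        )
    n = len(natural)
    grad = pd.DataFrame(
        np.zeros((n, N_TRANSITION_COEF)),
        columns=TRANSITION_DESIGN_COLUMNS,
        index=natural.index,
    )
    grad[variable] = 1.0
    if variable in ("phys_encounters", "tel_encounters"):
        prefix = "phys" if variable == "phys_encounters" else "tel"
        for m in TRANSITION_MODIFIERS:
            grad[f"{prefix}_x_{m}"] = natural[m].to_numpy(float)
    else:
        grad[f"phys_x_{variable}"] = natural["phys_encounters"].to_numpy(float)
        grad[f"tel_x_{variable}"] = natural["tel_encounters"].to_numpy(float)
    return grad.to_numpy(float)
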