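"""Average marginal effects and the combined two-model contrast.

For the 9-category softmax with reference category D->D, the derivative of
category probability p_j with respect to covariate x_k is

    dp_j/dx_k = p_j * (d_j - sum_j' p_j' d_j'),    d_j = d(x'alpha_j)/dx_k,

with d_ref = 0; this is the closed form for the non-reference categories and
its negative-sum counterpart for the reference. The derivative of the linear
predictor runs through the encounter x covariate interaction products, so an
encounter's marginal effect depends on the sociodemographic profile at which
it is evaluated — which is exactly what the quartile-stratified AMEs
exploit. Derivatives sum to zero over the nine categories because the
probabilities sum to one.

Covariates that enter the model in logs can be reported per unit of the
natural-scale variable through the chain rule dp/dx = (1/x) dp/d(log x).

The combined contrast chains the two models: the encounter model prices a
sociodemographic quartile gap in expected encounters, and that encounter
difference is pushed through the transition model's probabilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .count_model import (
    ZeroInflatedPoissonResults,
    _patient_quartile_masks,
    encounter_quartile_contrast,
)
from .design import (
    TRANSITION_MAIN_TERMS,
    TRANSITION_TYPES,
    expand_transition_design,
    transition_design_gradient,
    transition_natural_frame,
)
from .transition_model import GlucoseTransitionResults, softmax_probs

__all__ = [
    "marginal_effect_analytic",
    "average_marginal_effect",
    "ame_by_quartile",
    "combined_contrast",
]

#: natural-scale aliases: effect per year of age / per dollar of income
_LEVEL_ALIASES = {"age": "log_age", "income": "log_income"}


def _resolve_variable(variable: str):
    """Map a requested variable to its design name and a level-scale flag."""
    if variable in TRANSITION_MAIN_TERMS:
        return variable, None
    if variable in _LEVEL_ALIASES:
        return _LEVEL_ALIASES[variable], variable
    raise KeyError(
        f"{variable!r} is not a transition-model covariate; expected one of "
        f"{TRANSITION_MAIN_TERMS} or a level alias {sorted(_LEVEL_ALIASES)}")


def marginal_effect_analytic(fit: GlucoseTransitionResults,
                             data: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Pointwise derivatives dp_j/dx for every observation and all nine
    transition types.

    ``data`` holds the natural covariates (a transition-observation table
    works); ``variable`` is a design covariate such as ``phys_encounters``
    or ``pct_highschool``, or one of the level aliases ``age`` / ``income``
    for effects per natural unit of a log-transformed covariate.
    """
    design_var, level_of = _resolve_variable(variable)
    natural = transition_natural_frame(data)
    X = expand_transition_design(natural).to_numpy(float)
    G = transition_design_gradient(natural, design_var)
    alpha = fit.alpha_matrix
    P = softmax_probs(alpha, X)
    d = np.zeros((len(natural), len(TRANSITION_TYPES)))
    d[:, 1:] = G @ alpha.T
    me = P * (d - (P * d).sum(axis=1, keepdims=True))
    if level_of is not None:
        if level_of not in data.columns:
            raise KeyError(
                f"level-scale effect for {level_of!r} needs the natural "
                f"column {level_of!r} in the data")
        me = me / data[level_of].to_numpy(float)[:, None]
    return pd.DataFrame(me, columns=TRANSITION_TYPES, index=data.index)


def average_marginal_effect(fit: GlucoseTransitionResults, data: pd.DataFrame,
                            variable: str, bootstrap_reps: int = 500,
                            seed: int = 0,
                            patient_col: str = "patient_id") -> pd.DataFrame:
    """AME of a covariate on each transition-type probability.

    The pointwise analytic derivatives are averaged over all observations;
    uncertainty comes from a seeded patient-level bootstrap of that average
    (patients resampled with replacement, the fitted coefficients held
    fixed). Returns one row per transition type with columns ``ame`` and
    ``se``; the ``ame`` column sums to zero.
    """
    if data.empty:
        raise ValueError("no observations to average over")
    me = marginal_effect_analytic(fit, data, variable)
    ame = me.mean(axis=0)
    se = pd.Series(np.nan, index=ame.index)
    if bootstrap_reps > 0 and patient_col in data.columns:
        rng = np.random.default_rng(seed)
        patients = data[patient_col].to_numpy()
        uniq = np.unique(patients)
        by_patient = {pid: me.to_numpy()[patients == pid].sum(axis=0)
                      for pid in uniq}
        counts = {pid: int((patients == pid).sum()) for pid in uniq}
        sums = np.vstack([by_patient[p] for p in uniq])
        ns = np.array([counts[p] for p in uniq])
        reps = np.empty((bootstrap_reps, me.shape[1]))
        for b in range(bootstrap_reps):
            pick = rng.integers(0, len(uniq), size=len(uniq))
            reps[b] = sums[pick].sum(axis=0) / ns[pick].sum()
        se = pd.Series(reps.std(axis=0, ddof=1), index=ame.index)
    out = pd.DataFrame({"ame": ame, "se": se})
    out.index.name = "transition"
    return out


def ame_by_quartile(fit: GlucoseTransitionResults, data: pd.DataFrame,
                    variable: str, stratifier: str,
                    bootstrap_reps: int = 0, seed: int = 0,
                    patient_col: str = "patient_id") -> pd.DataFrame:
    """AME computed within patient-weighted quartile strata of a
    sociodemographic covariate.

    Quartile cut points are taken over the per-patient values of
    ``stratifier``; boundary ties fall to the lower stratum. Returns a long
    table with one row per (stratum, transition type); stratum counts sum to
    the number of observations.
    """
    if stratifier not in data.columns:
        raise KeyError(f"stratifier {stratifier!r} not in data")
    per_patient = data.groupby(patient_col)[stratifier].first()
    qs = np.quantile(per_patient.to_numpy(float), [0.25, 0.50, 0.75])
    value = data[patient_col].map(per_patient).to_numpy(float)
    stratum = 1 + (value > qs[0]).astype(int) + (value > qs[1]) + (value > qs[2])
    rows = []
    for s in (1, 2, 3, 4):
        sub = data[stratum == s]
        if sub.empty:
            raise ValueError(f"quartile stratum {s} of {stratifier!r} is empty")
        tab = average_marginal_effect(fit, sub, variable,
                                      bootstrap_reps=bootstrap_reps,
                                      seed=seed, patient_col=patient_col)
        tab = tab.reset_index()
        tab.insert(0, "stratum", s)
        tab["n_obs"] = len(sub)
        rows.append(tab)
    return pd.concat(rows, ignore_index=True)


def combined_contrast(zip_fit: ZeroInflatedPoissonResults,
                      transition_fit: GlucoseTransitionResults,
                      panel: pd.DataFrame, transitions: pd.DataFrame,
                      socio_variable: str,
                      encounter_variable: str = "phys_encounters") -> dict:
    """Chain the two models: a sociodemographic quartile gap in expected
    encounters, pushed through the transition probabilities.

    Step 1 prices the quartile gap with the encounter model:
    ``encounter_delta`` is the change in model-implied expected encounters
    moving from the upper to the lower quartile of ``socio_variable``
    (typically negative — fewer encounters). Step 2 shifts every transition
    observation's encounter count by that delta (interaction products
    re-expanded), and averages the per-type probability changes; they sum to
    zero over the nine types. A 3x3 origin-conditional view of the same
    shift is included as a derived quantity.
    """
    if encounter_variable not in ("phys_encounters", "tel_encounters"):
        raise ValueError("encounter_variable must be phys_encounters or "
                         "tel_encounters")
    if not zip_fit.converged or not transition_fit.converged:
        raise ValueError("both model fits must have converged")
    q = encounter_quartile_contrast(zip_fit, panel, socio_variable)
    encounter_delta = q["mean_lower"] - q["mean_upper"]

    natural = transition_natural_frame(transitions)
    shifted = natural.copy()
    shifted[encounter_variable] = shifted[encounter_variable] + encounter_delta
    alpha = transition_fit.alpha_matrix
    P0 = softmax_probs(alpha, expand_transition_design(natural).to_numpy(float))
    P1 = softmax_probs(alpha, expand_transition_design(shifted).to_numpy(float))
    deltas = pd.Series((P1 - P0).mean(axis=0), index=TRANSITION_TYPES)

    cond = _conditional_delta(P0, P1)
    return {
        "socio_variable": socio_variable,
        "encounter_variable": encounter_variable,
        "encounter_delta": float(encounter_delta),
        "transition_deltas": deltas.to_dict(),
        "conditional_deltas": cond,
        "quartile_detail": q,
    }


def _conditional_delta(P0: np.ndarray, P1: np.ndarray) -> dict:
    """Average change in origin-conditional destination probabilities."""
    out = {}
    for origin in ("N", "P", "D"):
        cols = [TRANSITION_TYPES.index(f"{origin}->{d}") for d in ("N", "P", "D")]
        c0 = P0[:, cols] / P0[:, cols].sum(axis=1, keepdims=True)
        c1 = P1[:, cols] / P1[:, cols].sum(axis=1, keepdims=True)
        diff = (c1 - c0).mean(axis=0)
        for j, dest in enumerate(("N", "P", "D")):
            out[f"{origin}->{dest}"] = float(diff[j])
    return out
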