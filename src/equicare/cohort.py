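"""Cohort preparation: diagnosis filters, glucose states, transition pairs,
and the descriptive hypothesis tests.

The study population is adult type 2 diabetes patients identified by ICD-10
code E11. Records coded E08/E09/E10 (diabetes secondary to other conditions,
drug-induced diabetes, type 1) and O24/E13 (gestational and other specified
diabetes) are excluded, as are patients observed in too small a fraction of
the six-month observation timeframe. Fasting plasma glucose is discretised
into the diagnostic states N (<100 mg/dl), P (100-125 mg/dl, both endpoints
prediabetic) and D (>125 mg/dl).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import STATES, TRANSITION_MODIFIERS

__all__ = [
    "RETAINED_CODES",
    "EXCLUDED_CODES",
    "classify_state",
    "filter_cohort",
    "FilterReport",
    "build_transitions",
    "prepare_panel",
    "descriptive_tests",
    "hotelling_t2",
]

#: ICD-10-style primary diabetes codes present in the raw panel
ALL_CODES = ["E08", "E09", "E10", "E11", "O24", "E13"]
EXCLUDED_CODES = ["E08", "E09", "E10", "O24", "E13"]
RETAINED_CODES = ["E11"]


# ---------------------------------------------------------------------------
# glucose states


def classify_state(glucose):
    """Map fasting plasma glucose (mg/dl) to the states N, P or D.

    N for values below 100; P for 100-125 inclusive on both ends; D above
    125. Accepts a scalar or array; raises on non-positive or missing input.
    """
    arr = np.asarray(glucose, float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("glucose must be positive and finite (mg/dl)")
    out = np.where(arr < 100.0, "N", np.where(arr <= 125.0, "P", "D"))
    if np.isscalar(glucose) or arr.ndim == 0:
        return str(out)
    return out


# ---------------------------------------------------------------------------
# cohort filters


@dataclass
class FilterReport:
    """Reconciling count report for the cohort filters.

    Counts are in patients; ``n_retained = n_input - sum(code removals) -
    n_removed_incomplete`` always holds. ``gender_homogeneity`` is a purely
    diagnostic chi-square test that completeness-removed patients do not
    differ systematically in gender from retained ones.
    """

    n_input: int
    n_removed_by_code: dict
    n_removed_incomplete: int
    n_retained: int
    completeness_threshold: float
    gender_homogeneity: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        return (self.n_input == sum(self.n_removed_by_code.values())
                + self.n_removed_incomplete + self.n_retained)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_by_code": dict(self.n_removed_by_code),
            "n_removed_incomplete": self.n_removed_incomplete,
            "n_retained": self.n_retained,
            "completeness_threshold": self.completeness_threshold,
            "gender_homogeneity": dict(self.gender_homogeneity),
        }


def filter_cohort(panel: pd.DataFrame,
                  completeness_threshold: float = 0.80
                  ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the diagnosis-code and record-completeness filters.

    A patient is retained when their code is E11 *and* they are observed in
    strictly more than ``completeness_threshold`` of the observation
    timeframe (the span from the earliest to the latest period present in
    the panel). Exclusions by code are counted before completeness, so each
    removed patient lands in exactly one bucket.
    """
    if not 0.0 < completeness_threshold <= 1.0:
        raise ValueError("completeness threshold must lie in (0, 1]")
    if panel.empty:
        report = FilterReport(0, {c: 0 for c in EXCLUDED_CODES}, 0, 0,
                              completeness_threshold)
        return panel.copy(), report

    codes = panel.groupby("patient_id")["icd_code"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "_mixed_")
    if (codes == "_mixed_").any():
        raise ValueError("patients with more than one disease code found")
    unknown = sorted(set(codes) - set(ALL_CODES))
    if unknown:
        raise ValueError(f"unknown disease codes {unknown}: schema violation")

    n_input = len(codes)
    removed_by_code = {c: int((codes == c).sum()) for c in EXCLUDED_CODES}
    code_ok = codes[codes.isin(RETAINED_CODES)].index

    span = int(panel["period"].max() - panel["period"].min() + 1)
    n_obs = panel.groupby("patient_id")["period"].nunique()
    frac = n_obs / span
    complete = frac[frac > completeness_threshold].index

    keep = code_ok.intersection(complete)
    n_removed_incomplete = int(len(code_ok) - len(keep))
    filtered = panel[panel["patient_id"].isin(keep)].copy()

    report = FilterReport(
        n_input=n_input,
        n_removed_by_code=removed_by_code,
        n_removed_incomplete=n_removed_incomplete,
        n_retained=int(len(keep)),
        completeness_threshold=completeness_threshold,
        gender_homogeneity=_gender_homogeneity(panel, code_ok, keep),
    )
    assert report.reconciles()
    return filtered, report


def _gender_homogeneity(panel, code_ok, keep) -> dict:
    """Chi-square homogeneity of gender between completeness-removed and
    retained patients (diagnostic only)."""
    if "male" not in panel.columns:
        return {}
    removed = code_ok.difference(keep)
    if len(removed) == 0 or len(keep) == 0:
        return {}
    male = panel.groupby("patient_id")["male"].first()
    table = np.array([
        [int(male[keep].sum()), int((1 - male[keep]).sum())],
        [int(male[removed].sum()), int((1 - male[removed]).sum())],
    ])
    if (table.sum(axis=0) == 0).any():
        return {}
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p), "dof": int(dof)}


# ---------------------------------------------------------------------------
# transition observations


def build_transitions(panel: pd.DataFrame) -> pd.DataFrame:
    """One transition observation per consecutive observed period pair.

    Requires ``patient_id``, ``period``, ``glucose``, the two encounter
    counts, ``age`` and the joined ZIP-code covariates. Pairs spanning a gap
    in the period index are not emitted. The encounter covariates of a
    transition t -> t+1 are the counts of the *origin* period t, matching a
    model in which care contact during a period shapes the state at its end.
    """
    if panel.duplicated(["patient_id", "period"]).any():
        raise ValueError("duplicate (patient, period) rows in panel")
    need = ["glucose", "phys_encounters", "tel_encounters", "age",
            "pct_white", "pct_black", "income", "pct_highschool",
            "pct_college"]
    missing = [c for c in need if c not in panel.columns]
    if missing:
        raise KeyError(f"panel missing columns {missing} "
                       "(join ZIP covariates first)")
    df = panel.sort_values(["patient_id", "period"])
    nxt = df.groupby("patient_id").shift(-1)
    consecutive = (nxt["period"] - df["period"]) == 1
    origin = pd.Series(classify_state(df["glucose"].to_numpy()),
                       index=df.index)
    dest_glucose = nxt["glucose"]
    mask = consecutive.fillna(False).to_numpy()
    out = pd.DataFrame({
        "patient_id": df.loc[mask, "patient_id"].to_numpy(),
        "period": df.loc[mask, "period"].to_numpy(),
        "origin": origin[mask].to_numpy(),
        "destination": classify_state(dest_glucose[mask].to_numpy(float)),
    })
    out["transition"] = out["origin"] + "->" + out["destination"]
    for c in ["phys_encounters", "tel_encounters"]:
        out[c] = df.loc[mask, c].to_numpy()
    out["log_age"] = np.log(df.loc[mask, "age"].to_numpy(float))
    for c in ["pct_white", "pct_black", "pct_highschool", "pct_college"]:
        out[c] = df.loc[mask, c].to_numpy(float)
    out["log_income"] = np.log(df.loc[mask, "income"].to_numpy(float))
    # keep natural-scale columns for quartile stratification downstream
    out["income"] = df.loc[mask, "income"].to_numpy(float)
    out["age"] = df.loc[mask, "age"].to_numpy(float)
    return out.reset_index(drop=True)


def prepare_panel(panel: pd.DataFrame, zip_table: pd.DataFrame,
                  completeness_threshold: float = 0.80):
    """Filter the cohort, join ZIP covariates, and build lagged rows.

    Returns ``(lagged, transitions, report)``: ``lagged`` has one row per
    patient-period with a preceding observed period (carrying
    ``glucose_lag`` / ``cholesterol_lag`` for the encounter model),
    ``transitions`` is the transition-observation table.
    """
    joined = panel.merge(zip_table, on="zip_id", how="left", validate="m:1")
    if joined["income"].isna().any():
        raise ValueError("panel references zip_id values absent from the "
                         "ZIP table")
    filtered, report = filter_cohort(joined, completeness_threshold)
    df = filtered.sort_values(["patient_id", "period"])
    prev = df.groupby("patient_id").shift(1)
    lagged = df.loc[(df["period"] - prev["period"]) == 1].copy()
    lagged["glucose_lag"] = prev.loc[lagged.index, "glucose"]
    lagged["cholesterol_lag"] = prev.loc[lagged.index, "cholesterol"]
    transitions = build_transitions(filtered)
    return lagged.reset_index(drop=True), transitions, report


# ---------------------------------------------------------------------------
# descriptive tests


def one_sample_t(x, mu0: float, alternative: str = "greater") -> dict:
    """One-sample t statistic t = (xbar - mu0) / (s / sqrt(n))."""
    v = np.asarray(x, float)
    if len(v) < 2:
        raise ValueError("need >= 2 observations for a t test")
    t, p = stats.ttest_1samp(v, mu0, alternative=alternative)
    return {"t": float(t), "p": float(p), "mu0": float(mu0),
            "mean": float(v.mean()), "n": int(len(v))}


def hotelling_t2(x: np.ndarray, y: np.ndarray) -> dict:
    """Hotelling's T^2 for two independent mean vectors, pooled covariance.

    Raises on a singular pooled covariance rather than regularising.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    p = x.shape[1]
    if nx < 2 or ny < 2:
        raise ValueError("need at least 2 observations per group")
    diff = x.mean(axis=0) - y.mean(axis=0)
    S = ((nx - 1) * np.cov(x, rowvar=False)
         + (ny - 1) * np.cov(y, rowvar=False)) / (nx + ny - 2)
    S = np.atleast_2d(S)
    if np.linalg.cond(S) > 1e12:
        raise np.linalg.LinAlgError("singular pooled covariance")
    t2 = float(nx * ny / (nx + ny) * diff @ np.linalg.solve(S, diff))
    f_stat = t2 * (nx + ny - p - 1) / (p * (nx + ny - 2))
    pval = float(stats.f.sf(f_stat, p, nx + ny - p - 1))
    return {"t2": t2, "f": float(f_stat), "df1": p, "df2": nx + ny - p - 1,
            "p": pval}


def descriptive_tests(panel: pd.DataFrame,
                      clinical_labels: pd.Series | None = None) -> dict:
    """The descriptive-table hypothesis tests.

    * one-sample t statistics of mean glucose against the 125 and 100 mg/dl
      diagnostic thresholds and of LDL cholesterol against 100 mg/dl
      (one-sided p, H0: mean below threshold);
    * chi-square goodness of fit of gender and insurance against a discrete
      uniform distribution;
    * Hotelling T^2 between consecutive clinical-cluster mean vectors on
      (glucose, cholesterol), when per-patient cluster labels are supplied.
    """
    out: dict = {}
    for name, col, mu0 in [("glucose_vs_125", "glucose", 125.0),
                           ("glucose_vs_100", "glucose", 100.0),
                           ("cholesterol_vs_100", "cholesterol", 100.0)]:
        out[name] = one_sample_t(panel[col].to_numpy(float), mu0)

    per_patient = panel.groupby("patient_id").first()
    for name, col in [("gender_uniform", "male"),
                      ("insurance_uniform", "insurance")]:
        if col not in per_patient:
            continue
        counts = per_patient[col].value_counts().sort_index().to_numpy(float)
        chi2, p = stats.chisquare(counts)
        out[name] = {"chi2": float(chi2), "p": float(p),
                     "dof": int(len(counts) - 1)}

    if clinical_labels is not None:
        feats = panel.groupby("patient_id")[["glucose", "cholesterol"]].mean()
        labels = clinical_labels.reindex(feats.index)
        pairs = {}
        ks = sorted(labels.dropna().unique())
        for a, b in zip(ks[:-1], ks[1:]):
            xa = feats[labels == a].to_numpy()
            xb = feats[labels == b].to_numpy()
            pairs[f"cluster_{int(b)}_vs_{int(a)}"] = hotelling_t2(xb, xa)
        out["hotelling"] = pairs
    return out
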