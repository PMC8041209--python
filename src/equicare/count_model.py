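"""Encounter count models.

The primary model is a zero-inflated Poisson (ZIP) regression of six-month
encounter counts (physical or telephonic) on lagged clinical measures,
demographics, insurance group, clinical-cluster dummies and ZIP-code
sociodemographics. The count mixture has two components: with probability
``pi`` an observation is a structural zero (a patient out of contact with the
system for reasons the covariates do not carry), otherwise the count is
Poisson with rate ``lambda = exp(x' beta)``:

    P(y = 0) = pi + (1 - pi) * exp(-lambda)
    P(y = k) = (1 - pi) * Poisson(k; lambda),   k >= 1

``pi`` is a single scalar (an intercept-only inflation component). A
zero-truncated Poisson fit on the positive counts is provided as the
robustness variant (the count part of a hurdle model).

Both models are maximum-likelihood fits with analytic gradients; covariates
are standardized internally for optimisation and estimates mapped back to the
natural scale, so reported coefficients always refer to the columns of the
design as built by :func:`equicare.design.encounter_design_matrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

from .design import (
    CLUSTER_DUMMY_TERMS,
    ENCOUNTER_DESIGN_COLUMNS,
    encounter_design_matrix,
)

__all__ = [
    "ZipPoissonParams",
    "ZeroInflatedPoissonModel",
    "ZeroInflatedPoissonResults",
    "TruncatedPoissonModel",
    "zero_inflated_poisson_loglik",
    "truncated_poisson_loglik",
    "fit_per_cluster",
    "encounter_quartile_contrast",
]

_ETA_CLIP = 30.0  # linear-predictor guard against exp overflow


# ---------------------------------------------------------------------------
# parameter container


@dataclass
class ZipPoissonParams:
    """Ground-truth / estimated parameters of the encounter ZIP model.

    ``beta`` holds (intercept, log cholesterol, log glucose, log age, male);
    ``alpha`` the clinical-cluster dummies (clusters 2..4, cluster 1 is the
    reference); ``tau`` the insurance-group dummies (groups 2..13, group 1
    reference); ``gamma`` the six community covariates (log population,
    white %, African American %, log income, high-school %, college %);
    ``pi`` the structural-zero probability.
    """

    beta: np.ndarray
    alpha: np.ndarray
    tau: np.ndarray
    gamma: np.ndarray
    pi: float

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.alpha = np.asarray(self.alpha, float)
        self.tau = np.asarray(self.tau, float)
        self.gamma = np.asarray(self.gamma, float)
        if self.beta.shape != (5,):
            raise ValueError("beta must hold 5 patient-level coefficients")
        if self.alpha.shape != (3,):
            raise ValueError("alpha must hold 3 clinical-cluster dummies")
        if self.tau.shape != (12,):
            raise ValueError("tau must hold 12 insurance-group dummies")
        if self.gamma.shape != (6,):
            raise ValueError("gamma must hold 6 community coefficients")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")

    def coef_vector(self) -> np.ndarray:
        """Full coefficient vector in the canonical design order (26,)."""
        return np.concatenate([self.beta, self.alpha, self.tau, self.gamma])

    @classmethod
    def from_vector(cls, coef: np.ndarray, pi: float) -> "ZipPoissonParams":
        coef = np.asarray(coef, float)
        if coef.shape != (26,):
            raise ValueError("coefficient vector must have length 26")
        return cls(beta=coef[:5], alpha=coef[5:8], tau=coef[8:20],
                   gamma=coef[20:26], pi=float(pi))

    @property
    def names(self) -> list[str]:
        return list(ENCOUNTER_DESIGN_COLUMNS)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "alpha": self.alpha.tolist(),
            "tau": self.tau.tolist(),
            "gamma": self.gamma.tolist(),
            "pi": float(self.pi),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ZipPoissonParams":
        required = {"beta", "alpha", "tau", "gamma", "pi"}
        missing = required - set(d)
        if missing:
            raise KeyError(f"ZipPoissonParams record missing fields {sorted(missing)}")
        return cls(beta=np.asarray(d["beta"]), alpha=np.asarray(d["alpha"]),
                   tau=np.asarray(d["tau"]), gamma=np.asarray(d["gamma"]),
                   pi=float(d["pi"]))


# ---------------------------------------------------------------------------
# likelihood kernels


def zero_inflated_poisson_loglik(y: np.ndarray, lam: np.ndarray,
                                 pi: float) -> float:
    """Sum of ZIP log-likelihood contributions.

    Zero counts contribute ``log(pi + (1 - pi) e^-lam)``; positive counts
    ``log(1 - pi) - lam + y log lam - log y!``. Valid for ``pi`` in [0, 1]
    (at ``pi = 1`` every positive count has probability zero).
    """
    y = np.asarray(y)
    lam = np.broadcast_to(np.asarray(lam, float), y.shape)
    _check_counts(y)
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    zero = y == 0
    with np.errstate(divide="ignore"):
        log_pi = np.log(pi)
        log_1mpi = np.log1p(-pi)
    lz = np.logaddexp(log_pi, log_1mpi - lam[zero]) if zero.any() else 0.0
    ll = float(np.sum(lz))
    yp = y[~zero]
    lp = lam[~zero]
    if yp.size:
        if pi == 1.0:
            return -np.inf
        ll += float(np.sum(log_1mpi - lp + yp * np.log(lp)
                           - special.gammaln(yp + 1.0)))
    return ll


def truncated_poisson_loglik(y: np.ndarray, lam: np.ndarray) -> float:
    """Zero-truncated Poisson log-likelihood: P(y | y > 0)."""
    y = np.asarray(y)
    lam = np.broadcast_to(np.asarray(lam, float), y.shape)
    _check_counts(y)
    if np.any(y == 0):
        raise ValueError("truncated Poisson likelihood is defined for y >= 1")
    # log(1 - e^-lam) via expm1 for small rates
    log_norm = np.log(-np.expm1(-lam))
    return float(np.sum(-lam + y * np.log(lam) - special.gammaln(y + 1.0)
                        - log_norm))


def _check_counts(y: np.ndarray) -> None:
    if np.any(y < 0) or not np.issubdtype(np.asarray(y).dtype, np.integer):
        yf = np.asarray(y, float)
        if np.any(yf < 0) or np.any(yf != np.round(yf)):
            raise ValueError("counts must be non-negative integers")


# ---------------------------------------------------------------------------
# internal standardization helpers


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center/scale non-constant columns; constant columns pass through."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    mu = np.where(keep, mu, 0.0)
    sd = np.where(keep, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _destandardize_jacobian(mu: np.ndarray, sd: np.ndarray,
                            const_idx: int = 0) -> np.ndarray:
    """Linear map from standardized-scale coefficients to natural scale.

    With z_j = (x_j - mu_j) / sd_j the natural coefficients are
    b_j = b*_j / sd_j and the intercept absorbs -sum b*_j mu_j / sd_j.
    """
    p = len(sd)
    J = np.zeros((p, p))
    for j in range(p):
        if j == const_idx:
            J[j, j] = 1.0
        else:
            J[j, j] = 1.0 / sd[j]
            J[const_idx, j] = -mu[j] / sd[j]
    return J


def _as_design(exog, exog_names) -> tuple[np.ndarray, list[str]]:
    if isinstance(exog, pd.DataFrame):
        names = list(exog.columns)
        X = exog.to_numpy(float)
    else:
        X = np.asarray(exog, float)
        names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(X.shape[1])
        ]
    if len(names) != X.shape[1]:
        raise ValueError("exog_names length does not match design width")
    return X, names


# ---------------------------------------------------------------------------
# the ZIP model


class ZeroInflatedPoissonModel:
    """Zero-inflated Poisson regression with a scalar inflation probability.

    Parameters
    ----------
    counts : array-like of non-negative int
        Encounter counts, one per patient-period row.
    exog : DataFrame or ndarray
        Design matrix including a ``const`` column.
    """

    def __init__(self, counts, exog, exog_names=None):
        self.endog = np.asarray(counts)
        _check_counts(self.endog)
        self.endog = self.endog.astype(np.int64)
        self.exog, self.exog_names = _as_design(exog, exog_names)
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("counts and design have different lengths")
        self.nobs = self.endog.shape[0]
        self.k_coef = self.exog.shape[1]

    # -- construction from a prepared panel ---------------------------------
    @classmethod
    def from_panel(cls, panel: pd.DataFrame, response: str = "phys_encounters",
                   drop_cluster_dummies: bool = False,
                   drop_degenerate: bool = False) -> "ZeroInflatedPoissonModel":
        """Build counts + design from a prepared (lagged, ZIP-joined) panel.

        ``drop_degenerate`` removes dummy columns with no variation (e.g. an
        insurance group absent from a cluster stratum) instead of letting the
        rank check fail.
        """
        X = encounter_design_matrix(panel)
        if drop_cluster_dummies:
            X = X.drop(columns=CLUSTER_DUMMY_TERMS)
        if drop_degenerate:
            degenerate = [c for c in X.columns
                          if c != "const" and X[c].nunique() == 1]
            X = X.drop(columns=degenerate)
        return cls(panel[response].to_numpy(), X)

    # -- likelihood ----------------------------------------------------------
    def _eta(self, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
        return np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at ``params = [logit(pi), beta...]`` (natural scale)."""
        q, beta = params[0], params[1:]
        lam = np.exp(self._eta(beta, self.exog))
        return zero_inflated_poisson_loglik(self.endog, lam, special.expit(q))

    def score(self, params: np.ndarray) -> np.ndarray:
        return self._score(params, self.exog)

    def _loglike_std(self, params, Z):
        q, beta = params[0], params[1:]
        lam = np.exp(self._eta(beta, Z))
        return zero_inflated_poisson_loglik(self.endog, lam, special.expit(q))

    def _score(self, params: np.ndarray, X: np.ndarray) -> np.ndarray:
        q, beta = params[0], params[1:]
        y = self.endog
        eta = self._eta(beta, X)
        lam = np.exp(eta)
        sig_q = special.expit(q)        # pi
        sig_nq = special.expit(-q)      # 1 - pi
        zero = y == 0
        g = np.zeros_like(params)
        resid = np.where(zero, 0.0, y - lam)  # positive-row score on beta
        if zero.any():
            a = -np.logaddexp(0.0, -q)                      # log pi
            c = -np.logaddexp(0.0, q) - lam[zero]           # log(1-pi) - lam
            l0 = np.logaddexp(a, c)
            w = np.exp(a - l0)                              # P(structural | y=0)
            g[0] += float(np.sum(w * sig_nq - (1.0 - w) * sig_q))
            resid[zero] = -(1.0 - w) * lam[zero]
        g[0] += -sig_q * float(np.sum(~zero))
        g[1:] = X.T @ resid
        return g

    # -- fitting -------------------------------------------------------------
    def fit(self, start_params=None, gtol: float = 1e-6,
            maxiter: int = 500) -> "ZeroInflatedPoissonResults":
        """Maximise the likelihood by BFGS with an analytic gradient.

        Convergence is declared when the infinity norm of the gradient of the
        *mean* log-likelihood falls below ``gtol``. Standard errors come from
        the inverse observed information at the optimum.
        """
        y = self.endog
        if not (y == 0).any():
            raise ValueError("no zero counts: the inflation probability is "
                             "unidentifiable (fit a plain Poisson instead)")
        if not (y > 0).any():
            raise ValueError("all counts are zero: the Poisson rate is "
                             "unidentifiable")
        Z, mu, sd = _standardize(self.exog)
        if np.linalg.matrix_rank(Z) < self.k_coef:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        n = self.nobs

        if start_params is None:
            start_params = self._warm_start(Z)

        def neg(params):
            return -self._loglike_std(params, Z) / n

        def grad(params):
            return -self._score(params, Z) / n

        res = optimize.minimize(neg, start_params, jac=grad, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        params_std = res.x
        gnorm = float(np.max(np.abs(grad(params_std))))
        converged = gnorm < max(gtol, 1e-5)

        hess = numdiff.approx_hess(params_std, neg)
        cov_std = np.linalg.inv(hess) / n
        # map (q, beta_std) -> (q, beta_natural)
        J = np.zeros((self.k_coef + 1, self.k_coef + 1))
        J[0, 0] = 1.0
        J[1:, 1:] = _destandardize_jacobian(mu, sd)
        full_nat = J @ params_std
        cov_nat = J @ cov_std @ J.T
        return ZeroInflatedPoissonResults(
            model=self, params_full=full_nat, cov=cov_nat,
            llf=self._loglike_std(params_std, Z), converged=converged,
            grad_norm=gnorm, niter=int(res.nit),
        )

    def _warm_start(self, Z: np.ndarray) -> np.ndarray:
        """Poisson-regression warm start plus an excess-zero estimate of pi."""
        import statsmodels.api as sm

        pois = sm.GLM(self.endog, Z, family=sm.families.Poisson()).fit()
        lam = pois.predict(Z)
        p0_obs = float(np.mean(self.endog == 0))
        p0_pois = float(np.mean(np.exp(-lam)))
        pi0 = (p0_obs - p0_pois) / max(1.0 - p0_pois, 1e-8)
        pi0 = float(np.clip(pi0, 0.02, 0.90))
        return np.concatenate([[special.logit(pi0)], np.asarray(pois.params)])


class ZeroInflatedPoissonResults:
    """MLE results: natural-scale coefficients, SEs, Wald CIs, predictions."""

    def __init__(self, model, params_full, cov, llf, converged, grad_norm,
                 niter):
        self.model = model
        self._q = float(params_full[0])
        self.pi = float(special.expit(self._q))
        self.params = pd.Series(params_full[1:], index=model.exog_names)
        self.cov = cov
        self.llf = float(llf)
        self.nobs = model.nobs
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.niter = niter
        se_full = np.sqrt(np.maximum(np.diag(cov), 0.0))
        self.bse = pd.Series(se_full[1:], index=model.exog_names)
        # delta method: d pi / d q = pi (1 - pi)
        self.pi_se = float(se_full[0] * self.pi * (1.0 - self.pi))

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse}
        )

    def tvalues(self) -> pd.Series:
        return self.params / self.bse.replace(0.0, np.nan)

    def predict_rate(self, exog=None) -> np.ndarray:
        """Poisson rate lambda for each row."""
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return np.exp(np.clip(X @ self.params.to_numpy(), -_ETA_CLIP, _ETA_CLIP))

    def predict_mean(self, exog=None) -> np.ndarray:
        """Marginal expected count (1 - pi) * lambda."""
        return (1.0 - self.pi) * self.predict_rate(exog)

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table: term, estimate, se, ci_low, ci_high, p."""
        ci = self.conf_int()
        z = self.params / self.bse.replace(0.0, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "ci_low": ci["lower"].to_numpy(),
            "ci_high": ci["upper"].to_numpy(),
            "p": p,
        }).reset_index(drop=True)

    def summary(self) -> str:
        lines = [
            "Zero-inflated Poisson encounter model",
            f"  n obs: {self.nobs}   log-likelihood: {self.llf:.2f}   "
            f"converged: {self.converged}",
            f"  structural-zero probability pi: {self.pi:.4f} "
            f"(se {self.pi_se:.4f})",
            "",
            self.to_frame().to_string(
                index=False, float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# zero-truncated Poisson (positive-count robustness variant)


class TruncatedPoissonModel:
    """Zero-truncated Poisson regression on the positive counts only.

    This is the count half of a hurdle reading of the encounter process:
    conditional on at least one encounter, counts follow
    ``P(y | y > 0) = e^-lam lam^y / (y! (1 - e^-lam))``.
    """

    def __init__(self, counts, exog, exog_names=None):
        y = np.asarray(counts)
        _check_counts(y)
        X, names = _as_design(exog, exog_names)
        pos = y > 0
        if not pos.any():
            raise ValueError("no positive counts to fit the truncated model on")
        self.endog = y[pos].astype(np.int64)
        self.exog = X[pos]
        self.exog_names = names
        self.nobs = int(pos.sum())
        self.k_coef = self.exog.shape[1]

    @classmethod
    def from_panel(cls, panel, response="phys_encounters",
                   drop_cluster_dummies=False, drop_degenerate=False):
        X = encounter_design_matrix(panel)
        if drop_cluster_dummies:
            X = X.drop(columns=CLUSTER_DUMMY_TERMS)
        if drop_degenerate:
            degenerate = [c for c in X.columns
                          if c != "const" and X[c].nunique() == 1]
            X = X.drop(columns=degenerate)
        return cls(panel[response].to_numpy(), X)

    def loglike(self, beta: np.ndarray) -> float:
        lam = np.exp(np.clip(self.exog @ beta, -_ETA_CLIP, _ETA_CLIP))
        return truncated_poisson_loglik(self.endog, lam)

    def _loglike_std(self, beta, Z):
        lam = np.exp(np.clip(Z @ beta, -_ETA_CLIP, _ETA_CLIP))
        return truncated_poisson_loglik(self.endog, lam)

    def _score_std(self, beta, Z):
        lam = np.exp(np.clip(Z @ beta, -_ETA_CLIP, _ETA_CLIP))
        # E[y | y>0] = lam / (1 - e^-lam)
        mean_trunc = lam / (-np.expm1(-lam))
        return Z.T @ (self.endog - mean_trunc)

    def fit(self, gtol: float = 1e-6, maxiter: int = 500):
        Z, mu, sd = _standardize(self.exog)
        if np.linalg.matrix_rank(Z) < self.k_coef:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        n = self.nobs
        import statsmodels.api as sm

        start = np.asarray(
            sm.GLM(self.endog, Z, family=sm.families.Poisson()).fit().params)

        neg = lambda b: -self._loglike_std(b, Z) / n
        grad = lambda b: -self._score_std(b, Z) / n
        res = optimize.minimize(neg, start, jac=grad, method="BFGS",
                                options={"gtol": gtol, "maxiter": maxiter})
        gnorm = float(np.max(np.abs(grad(res.x))))
        hess = numdiff.approx_hess(res.x, neg)
        cov_std = np.linalg.inv(hess) / n
        J = _destandardize_jacobian(mu, sd)
        params_nat = J @ res.x
        cov_nat = J @ cov_std @ J.T
        return TruncatedPoissonResults(self, params_nat, cov_nat,
                                       self._loglike_std(res.x, Z),
                                       gnorm < max(gtol, 1e-5), gnorm,
                                       int(res.nit))


class TruncatedPoissonResults:
    def __init__(self, model, params, cov, llf, converged, grad_norm, niter):
        self.model = model
        self.params = pd.Series(params, index=model.exog_names)
        self.cov = cov
        self.bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)),
                             index=model.exog_names)
        self.llf = float(llf)
        self.nobs = model.nobs
        self.converged = bool(converged)
        self.grad_norm = float(grad_norm)
        self.niter = niter

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({"lower": self.params - z * self.bse,
                             "upper": self.params + z * self.bse})

    def predict_rate(self, exog=None) -> np.ndarray:
        X = self.model.exog if exog is None else np.asarray(exog, float)
        return np.exp(np.clip(X @ self.params.to_numpy(), -_ETA_CLIP, _ETA_CLIP))

    def to_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        z = self.params / self.bse.replace(0.0, np.nan)
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "term": self.params.index, "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(), "ci_low": ci["lower"].to_numpy(),
            "ci_high": ci["upper"].to_numpy(), "p": p,
        }).reset_index(drop=True)

    def summary(self) -> str:
        return ("Zero-truncated Poisson (positive-count) model\n"
                f"  n obs: {self.nobs}   log-likelihood: {self.llf:.2f}   "
                f"converged: {self.converged}\n\n"
                + self.to_frame().to_string(index=False,
                                            float_format=lambda v: f"{v: .4f}"))


# ---------------------------------------------------------------------------
# stratified fits and quartile contrasts


def fit_per_cluster(panel: pd.DataFrame, response: str = "phys_encounters",
                    cluster_col: str = "clinical_cluster",
                    min_obs_factor: int = 2, on_small: str = "raise",
                    **fit_kw) -> dict:
    """Refit the ZIP model within each clinical cluster (dummies dropped).

    A stratum with fewer than ``min_obs_factor * n_coefficients``
    observations raises by default; ``on_small='skip'`` leaves it out of the
    returned mapping instead (used by the pipeline, which records the skip).
    """
    out = {}
    for label, sub in panel.groupby(cluster_col, sort=True):
        model = ZeroInflatedPoissonModel.from_panel(
            sub, response=response, drop_cluster_dummies=True,
            drop_degenerate=True)
        if model.nobs < min_obs_factor * model.k_coef:
            if on_small == "skip":
                out[int(label)] = None
                continue
            raise ValueError(
                f"cluster {label}: only {model.nobs} observations for "
                f"{model.k_coef} coefficients")
        out[int(label)] = model.fit(**fit_kw)
    return out


def _patient_quartile_masks(panel: pd.DataFrame, variable: str,
                            patient_col: str = "patient_id"):
    """Row masks for the lower/upper patient-weighted quartiles of a variable.

    Quartile cut points are taken over the per-patient values (one value per
    patient), not over rows or ZIP codes; boundary ties go to the lower
    stratum.
    """
    per_patient = panel.groupby(patient_col)[variable].first()
    q1, q3 = np.quantile(per_patient.to_numpy(float), [0.25, 0.75])
    value = panel[patient_col].map(per_patient)
    lower = (value <= q1).to_numpy()
    upper = (value > q3).to_numpy()
    return lower, upper, float(q1), float(q3)


def encounter_quartile_contrast(results: ZeroInflatedPoissonResults,
                                panel: pd.DataFrame, variable: str,
                                patient_col: str = "patient_id") -> dict:
    """Expected-encounter gap between upper and lower quartiles of a
    sociodemographic variable.

    Averages the model-implied mean count ``(1 - pi) * lambda`` over the
    rows of patients in the upper quartile of ``variable`` and subtracts the
    same average over the lower quartile, all other covariates held at their
    observed values.
    """
    if variable not in panel.columns:
        raise KeyError(f"variable {variable!r} not in panel")
    lower, upper, q1, q3 = _patient_quartile_masks(panel, variable, patient_col)
    if not lower.any() or not upper.any():
        raise ValueError("empty quartile stratum")
    X = encounter_design_matrix(panel)
    if list(X.columns) != list(results.params.index):
        X = X[list(results.params.index)]
    mean_count = (1.0 - results.pi) * np.exp(
        np.clip(X.to_numpy(float) @ results.params.to_numpy(), -_ETA_CLIP,
                _ETA_CLIP))
    return {
        "variable": variable,
        "contrast": float(mean_count[upper].mean() - mean_count[lower].mean()),
        "mean_upper": float(mean_count[upper].mean()),
        "mean_lower": float(mean_count[lower].mean()),
        "cut_lower": q1,
        "cut_upper": q3,
        "n_lower": int(lower.sum()),
        "n_upper": int(upper.sum()),
    }
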