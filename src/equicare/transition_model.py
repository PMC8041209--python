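"""Glucose-state transition model.

Consecutive six-month periods define nine transition types among the fasting
plasma glucose states N (<100 mg/dl), P (100-125 mg/dl) and D (>125 mg/dl).
The transitions are pooled into a single 9-category multinomial logistic
regression with D->D as the reference category: for each non-reference
transition type j,

    log( P(type j) / P(D->D) ) = x' alpha_j

where x is the 21-term design of :mod:`equicare.design` (intercept, physical
and telephonic encounter counts, log age, four community covariates, and the
twelve encounter x covariate products). A 3x3 origin-conditional transition
matrix is available as a renormalised view of the pooled probabilities.

Fitting is full Newton-Raphson on internally standardized covariates with the
analytic gradient and Hessian; standard errors come from the inverse observed
information, mapped back to the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .design import (
    NONREF_TRANSITIONS,
    N_TRANSITION_COEF,
    REFERENCE_TRANSITION,
    STATES,
    TRANSITION_DESIGN_COLUMNS,
    TRANSITION_TYPES,
    expand_transition_design,
    transition_natural_frame,
)
from .count_model import _destandardize_jacobian, _standardize

__all__ = [
    "TransitionParams",
    "GlucoseTransitionModel",
    "GlucoseTransitionResults",
    "multinomial_loglik",
    "softmax_probs",
]

N_CATEGORIES = len(TRANSITION_TYPES)  # 9


@dataclass
class TransitionParams:
    """Coefficient matrix of the transition model.

    ``alpha`` has one 21-vector per non-reference transition type, in the
    order of :data:`equicare.design.NONREF_TRANSITIONS`; the reference
    category D->D has an implicit zero vector.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, float)
        if self.alpha.shape != (N_CATEGORIES - 1, N_TRANSITION_COEF):
            raise ValueError(
                f"alpha must have shape {(N_CATEGORIES - 1, N_TRANSITION_COEF)}")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=NONREF_TRANSITIONS,
                            columns=TRANSITION_DESIGN_COLUMNS)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionParams":
        if "alpha" not in d:
            raise KeyError("TransitionParams record missing field 'alpha'")
        return cls(alpha=np.asarray(d["alpha"], float))


def _linpred(alpha: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n, 9) linear predictors with the reference category fixed at zero."""
    eta = np.zeros((X.shape[0], N_CATEGORIES))
    eta[:, 1:] = X @ alpha.T
    return eta


def softmax_probs(alpha: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Category probabilities over the nine transition types, row-wise.

    Uses a log-sum-exp normaliser; rows sum to one to floating tolerance.
    """
    eta = _linpred(np.asarray(alpha, float), np.asarray(X, float))
    return np.exp(eta - logsumexp(eta, axis=1, keepdims=True))


def multinomial_loglik(alpha: np.ndarray, X: np.ndarray,
                       category_idx: np.ndarray) -> float:
    """Sum over observations of ``log p_category`` under the softmax."""
    category_idx = np.asarray(category_idx)
    if category_idx.min() < 0 or category_idx.max() >= N_CATEGORIES:
        raise ValueError("category index outside the nine transition types")
    eta = _linpred(np.asarray(alpha, float), np.asarray(X, float))
    lse = logsumexp(eta, axis=1)
    return float(np.sum(eta[np.arange(len(category_idx)), category_idx] - lse))


class GlucoseTransitionModel:
    """Pooled 9-category multinomial logit over glucose-state transitions.

    Parameters
    ----------
    categories : sequence of str or int
        Transition labels ("N->P" style) or indices into
        :data:`TRANSITION_TYPES`.
    exog : DataFrame or ndarray
        Expanded 21-column design (see
        :func:`equicare.design.expand_transition_design`).
    """

    def __init__(self, categories, exog, require_all_categories: bool = True):
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            self.exog = exog.to_numpy(float)
        else:
            self.exog = np.asarray(exog, float)
            self.exog_names = (list(TRANSITION_DESIGN_COLUMNS)
                               if self.exog.shape[1] == N_TRANSITION_COEF
                               else [f"x{j}" for j in range(self.exog.shape[1])])
        cats = np.asarray(categories)
        if cats.dtype.kind in "US O":
            lookup = {t: i for i, t in enumerate(TRANSITION_TYPES)}
            unknown = sorted(set(cats) - set(lookup))
            if unknown:
                raise ValueError(f"unknown transition labels {unknown}")
            self.category_idx = np.array([lookup[c] for c in cats])
        else:
            self.category_idx = cats.astype(int)
            if self.category_idx.min() < 0 or self.category_idx.max() >= N_CATEGORIES:
                raise ValueError("category index outside the nine transition types")
        if len(self.category_idx) != self.exog.shape[0]:
            raise ValueError("categories and design have different lengths")
        observed = np.bincount(self.category_idx, minlength=N_CATEGORIES)
        if require_all_categories and (observed == 0).any():
            missing = [TRANSITION_TYPES[i] for i in np.flatnonzero(observed == 0)]
            raise ValueError(
                f"transition types never observed: {missing}; their "
                "coefficients are unidentified")
        self.nobs = self.exog.shape[0]
        self.k_coef = self.exog.shape[1]
        self._Y = np.zeros((self.nobs, N_CATEGORIES))
        self._Y[np.arange(self.nobs), self.category_idx] = 1.0

    @classmethod
    def from_transitions(cls, transitions: pd.DataFrame,
                         **kw) -> "GlucoseTransitionModel":
        """Build from a transition-observation table (see
        :func:`equicare.cohort.build_transitions`)."""
        natural = transition_natural_frame(transitions)
        X = expand_transition_design(natural)
        return cls(transitions["transition"].to_numpy(), X, **kw)

    # -- likelihood ----------------------------------------------------------
    def loglike(self, alpha: np.ndarray) -> float:
        return multinomial_loglik(alpha, self.exog, self.category_idx)

    def score(self, alpha: np.ndarray) -> np.ndarray:
        """Gradient d loglik / d alpha, shape (8, 21)."""
        return self._score(np.asarray(alpha, float), self.exog)

    def _score(self, alpha, X):
        P = softmax_probs(alpha, X)
        return (self._Y - P)[:, 1:].T @ X

    def _hessian(self, alpha, X):
        """Observed information blocks of the flattened (8*21) parameter."""
        P = softmax_probs(alpha, X)
        p = X.shape[1]
        J = N_CATEGORIES - 1
        H = np.zeros((J * p, J * p))
        for j in range(J):
            pj = P[:, j + 1]
            for k in range(j, J):
                w = pj * ((1.0 if j == k else 0.0) - P[:, k + 1])
                block = -(X * w[:, None]).T @ X
                H[j * p:(j + 1) * p, k * p:(k + 1) * p] = block
                if k != j:
                    H[k * p:(k + 1) * p, j * p:(j + 1) * p] = block.T
        return H

    # -- fitting -------------------------------------------------------------
    def fit(self, gtol: float = 1e-6, maxiter: int = 200,
            separation_bound: float = 30.0) -> "GlucoseTransitionResults":
        """Newton-Raphson MLE with backtracking line search.

        Convergence: infinity norm of the gradient of the mean log-likelihood
        below ``gtol``. Coefficients diverging beyond ``separation_bound`` on
        the standardized scale flag (quasi-)complete separation.
        """
        Z, mu, sd = _standardize(self.exog)
        if np.linalg.matrix_rank(Z) < self.k_coef:
            raise np.linalg.LinAlgError("transition design is rank deficient")
        n = self.nobs
        p = self.k_coef
        J = N_CATEGORIES - 1
        alpha = np.zeros((J, p))
        ll = self.loglike_on(alpha, Z)
        niter = 0
        for niter in range(1, maxiter + 1):
            g = self._score(alpha, Z)
            if np.max(np.abs(g)) / n < gtol:
                break
            H = self._hessian(alpha, Z)
            # small Levenberg damping keeps the step well-posed when the
            # information is near-singular early on
            step = -np.linalg.solve(H - 1e-10 * n * np.eye(J * p),
                                    g.ravel()).reshape(J, p)
            # cap the Newton step: full steps from a poor start can overshoot
            # badly in weakly identified corners of the design
            maxstep = float(np.max(np.abs(step)))
            if maxstep > 2.0:
                step *= 2.0 / maxstep
            t = 1.0
            for _ in range(40):
                ll_new = self.loglike_on(alpha + t * step, Z)
                if ll_new >= ll - 1e-12 * abs(ll):
                    break
                t *= 0.5
            alpha = alpha + t * step
            ll = ll_new
        g = self._score(alpha, Z)
        gnorm = float(np.max(np.abs(g)) / n)
        # divergence of a standardized coefficient signals (quasi-)complete
        # separation in some corner of the design; it is reported alongside
        # the fit rather than voiding it, since the remaining coefficients
        # are still the MLE of their directions
        separated = bool(np.max(np.abs(alpha)) > separation_bound)
        converged = gnorm < max(gtol, 1e-5)
        H = self._hessian(alpha, Z)
        cov_std = np.linalg.inv(-H)
        # natural-scale map applied per category block
        Jmap = _destandardize_jacobian(mu, sd)
        alpha_nat = alpha @ Jmap.T
        big_J = np.kron(np.eye(J), Jmap)
        cov_nat = big_J @ cov_std @ big_J.T
        return GlucoseTransitionResults(
            model=self, alpha=alpha_nat, cov=cov_nat, llf=float(ll),
            converged=converged, separated=separated, grad_norm=gnorm,
            niter=niter)

    def loglike_on(self, alpha, X):
        return multinomial_loglik(alpha, X, self.category_idx)


class GlucoseTransitionResults:
    """Fitted transition model: 8x21 coefficients, SEs, CIs, predictions."""

    def __init__(self, model, alpha, cov, llf, converged, separated,
                 grad_norm, niter):
        self.model = model
        self.alpha_matrix = np.asarray(alpha, float)
        # canonical-design fits also expose the typed parameter container
        self.transition_params = (
            TransitionParams(alpha)
            if self.alpha_matrix.shape == (N_CATEGORIES - 1, N_TRANSITION_COEF)
            else None)
        self.params = pd.DataFrame(alpha, index=NONREF_TRANSITIONS,
                                   columns=model.exog_names)
        self.cov = cov
        p = model.k_coef
        se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(
            N_CATEGORIES - 1, p)
        self.bse = pd.DataFrame(se, index=NONREF_TRANSITIONS,
                                columns=model.exog_names)
        self.llf = float(llf)
        self.nobs = model.nobs
        self.converged = bool(converged)
        self.separated = bool(separated)
        self.grad_norm = float(grad_norm)
        self.niter = niter

    def conf_int(self, alpha_level: float = 0.05):
        z = stats.norm.ppf(1.0 - alpha_level / 2.0)
        return (self.params - z * self.bse, self.params + z * self.bse)

    # -- predictions ---------------------------------------------------------
    def predict_probs(self, exog=None) -> pd.DataFrame:
        """Pooled probabilities over the nine transition types (rows sum 1)."""
        X = self.model.exog if exog is None else np.asarray(exog, float)
        P = softmax_probs(self.alpha_matrix, X)
        return pd.DataFrame(P, columns=TRANSITION_TYPES)

    def predict_probs_natural(self, natural: pd.DataFrame) -> pd.DataFrame:
        """Same, from the eight natural covariates (interactions expanded
        internally)."""
        X = expand_transition_design(transition_natural_frame(natural))
        return self.predict_probs(X.to_numpy(float))

    def conditional_matrix(self, x_natural: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        """3x3 origin-conditional transition matrix at one covariate vector.

        Row i is P(destination | origin = i), the pooled probabilities
        renormalised within each origin state; rows sum to one.
        """
        if isinstance(x_natural, pd.DataFrame):
            X = expand_transition_design(
                transition_natural_frame(x_natural)).to_numpy(float)
        else:
            X = np.atleast_2d(np.asarray(x_natural, float))
        if X.shape[0] != 1:
            raise ValueError("conditional_matrix expects a single covariate row")
        probs = softmax_probs(self.alpha_matrix, X)[0]
        mat = np.empty((3, 3))
        for i, origin in enumerate(STATES):
            row = np.array([probs[TRANSITION_TYPES.index(f"{origin}->{d}")]
                            for d in STATES])
            mat[i] = row / row.sum()
        return pd.DataFrame(mat, index=STATES, columns=STATES)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long coefficient table with Wald CIs and p-values."""
        lo, hi = self.conf_int()
        rows = []
        for t in NONREF_TRANSITIONS:
            for c in self.model.exog_names:
                est, se = self.params.loc[t, c], self.bse.loc[t, c]
                z = est / se if se > 0 else np.nan
                rows.append({
                    "transition": t, "term": c, "estimate": est, "se": se,
                    "ci_low": lo.loc[t, c], "ci_high": hi.loc[t, c],
                    "p": 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                })
        return pd.DataFrame(rows)

    def significance_summary(self, alpha_level: float = 0.05) -> pd.DataFrame:
        """One row per transition type: which terms are significant at the
        given level (mirrors the usual published layout)."""
        tidy = self.to_frame()
        rows = []
        for t in NONREF_TRANSITIONS:
            sub = tidy[tidy["transition"] == t]
            sig = sub.loc[sub["p"] < alpha_level, "term"].tolist()
            rows.append({"transition": t, "n_significant": len(sig),
                         "significant_terms": ", ".join(sig)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (
            "Multinomial logistic glucose-transition model "
            f"(reference {REFERENCE_TRANSITION})\n"
            f"  n obs: {self.nobs}   log-likelihood: {self.llf:.2f}   "
            f"converged: {self.converged}   separation: {self.separated}\n")
        return head + "\n" + self.to_frame().to_string(
            index=False, float_format=lambda v: f"{v: .4f}")
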