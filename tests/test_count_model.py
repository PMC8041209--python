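"""Zero-inflated and zero-truncated Poisson encounter models."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats
from statsmodels.tools import numdiff

from equicare.count_model import (
    TruncatedPoissonModel,
    ZeroInflatedPoissonModel,
    ZipPoissonParams,
    encounter_quartile_contrast,
    fit_per_cluster,
    truncated_poisson_loglik,
    zero_inflated_poisson_loglik,
)
from equicare.design import ENCOUNTER_DESIGN_COLUMNS


def _random_data(n=300, p=3, pi=0.25, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = rng.normal(scale=0.4, size=p)
    beta[0] = 0.8
    lam = np.exp(X @ beta)
    y = rng.poisson(lam)
    y[rng.random(n) < pi] = 0
    return y, X, beta


class TestLikelihood:
    def test_hand_value_single_positive_term(self):
        # y=2, lam=1.5, pi=0.2
        expected = np.log(0.8) - 1.5 + 2 * np.log(1.5) - np.log(2.0)
        got = zero_inflated_poisson_loglik(np.array([2]), np.array([1.5]), 0.2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_pi_zero_reduces_to_poisson(self):
        y, X, beta = _random_data(pi=0.0)
        lam = np.exp(X @ beta)
        mine = zero_inflated_poisson_loglik(y, lam, 0.0)
        poisson = stats.poisson.logpmf(y, lam).sum()
        assert abs(mine - poisson) < 1e-10

    def test_zero_count_with_pi_one_contributes_zero(self):
        assert zero_inflated_poisson_loglik(np.array([0]),
                                            np.array([3.7]), 1.0) == 0.0

    def test_matches_statsmodels(self):
        from statsmodels.discrete.count_model import ZeroInflatedPoisson
        y, X, beta = _random_data(seed=3)
        pi = 0.3
        theta = np.concatenate([[special.logit(pi)], beta])
        sm_ll = ZeroInflatedPoisson(y, X, exog_infl=np.ones((len(y), 1)),
                                    inflation="logit").loglike(theta)
        mine = ZeroInflatedPoissonModel(y, X).loglike(theta)
        assert mine == pytest.approx(sm_ll, abs=1e-9)

    def test_analytic_score_matches_numerical(self):
        y, X, beta = _random_data(seed=5)
        m = ZeroInflatedPoissonModel(y, X)
        theta = np.concatenate([[0.3], beta])
        num = numdiff.approx_fprime(theta, m.loglike, centered=True)
        assert np.abs(m.score(theta) - num).max() < 1e-6 * (1 + np.abs(num).max())

    def test_counts_validated(self):
        with pytest.raises(ValueError):
            zero_inflated_poisson_loglik(np.array([-1]), np.array([1.0]), 0.1)
        with pytest.raises(ValueError):
            zero_inflated_poisson_loglik(np.array([1.5]), np.array([1.0]), 0.1)


class TestFit:
    def test_recovers_truth_on_study_panel(self, zip_fit, truth):
        tv = truth.zip_model_params.coef_vector()
        z = (zip_fit.params.to_numpy() - tv) / zip_fit.bse.to_numpy()
        assert zip_fit.converged
        assert np.abs(z).max() < 4.0
        assert zip_fit.pi == pytest.approx(truth.zip_model_params.pi,
                                           abs=4 * zip_fit.pi_se)

    def test_loglik_not_below_warm_start(self, prepared):
        import statsmodels.api as sm
        lagged, _, _ = prepared
        model = ZeroInflatedPoissonModel.from_panel(lagged, "phys_encounters")
        res = model.fit()
        glm = sm.GLM(model.endog, model.exog,
                     family=sm.families.Poisson()).fit()
        p0 = np.clip((np.mean(model.endog == 0)
                      - np.mean(np.exp(-glm.predict()))), 0.02, 0.9)
        start = np.concatenate([[special.logit(p0)], np.asarray(glm.params)])
        assert res.llf >= model.loglike(start)

    def test_mean_matching(self):
        """The fitted mixture mean (1 - pi) * mean(lambda) tracks the
        observed mean count (the score-equation residual is zero in
        expectation; at 20k observations it is well inside 1%)."""
        rng = np.random.default_rng(31)
        n = 20000
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        beta = np.array([1.0, 0.4, -0.3])
        y = rng.poisson(np.exp(X @ beta))
        y[rng.random(n) < 0.2] = 0
        res = ZeroInflatedPoissonModel(y, X).fit()
        assert res.predict_mean().mean() == pytest.approx(y.mean(), rel=0.01)

    def test_degenerate_counts_rejected(self):
        X = np.column_stack([np.ones(50), np.linspace(-1, 1, 50)])
        with pytest.raises(ValueError, match="all counts are zero"):
            ZeroInflatedPoissonModel(np.zeros(50, int), X).fit()
        with pytest.raises(ValueError, match="no zero counts"):
            ZeroInflatedPoissonModel(np.ones(50, int), X).fit()

    def test_rank_deficiency_detected(self):
        y = np.array([0, 1, 2, 0, 3] * 20)
        X = np.column_stack([np.ones(100), np.arange(100.0),
                             2 * np.arange(100.0)])
        with pytest.raises(np.linalg.LinAlgError):
            ZeroInflatedPoissonModel(y, X).fit()

    def test_pi_zero_truth_hits_boundary(self):
        """Data with no structural zeros drives pi to ~0 and the rate part
        to the plain Poisson solution."""
        import statsmodels.api as sm
        y, X, beta = _random_data(n=4000, pi=0.0, seed=7)
        res = ZeroInflatedPoissonModel(y, X).fit()
        assert res.pi < 0.03
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.abs(res.params.to_numpy() - glm.params).max() < 0.05


class TestTruncated:
    def test_loglik_hand_value(self):
        # P(y=2 | y>0), lam=1.5
        lam = 1.5
        expected = (-lam + 2 * np.log(lam) - np.log(2.0)
                    - np.log(1 - np.exp(-lam)))
        got = truncated_poisson_loglik(np.array([2]), np.array([lam]))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_recovery_from_truncated_draws(self):
        rng = np.random.default_rng(9)
        n = 6000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.7, 0.5])
        lam = np.exp(X @ beta)
        y = rng.poisson(lam)
        keep = y > 0  # truncation by rejection
        res = TruncatedPoissonModel(y[keep], X[keep]).fit()
        z = (res.params.to_numpy() - beta) / res.bse.to_numpy()
        assert res.converged and np.abs(z).max() < 4.0

    def test_large_rate_approaches_plain_poisson(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(11)
        n = 3000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([3.0, 0.2])  # lam ~ 20: truncation negligible
        y = rng.poisson(np.exp(X @ beta))
        pos = y > 0
        trunc = TruncatedPoissonModel(y[pos], X[pos]).fit()
        glm = sm.GLM(y[pos], X[pos], family=sm.families.Poisson()).fit()
        assert np.abs(trunc.params.to_numpy() - glm.params).max() < 1e-3

    def test_no_positive_counts_rejected(self):
        with pytest.raises(ValueError):
            TruncatedPoissonModel(np.zeros(10, int), np.ones((10, 1)))


class TestStratifiedAndContrast:
    def test_per_cluster_fits_recover_shared_truth(self, prepared, truth):
        lagged, _, _ = prepared
        fits = fit_per_cluster(lagged, "phys_encounters")
        assert set(fits) == {1, 2, 3, 4}
        coef = truth.zip_model_params
        for lab, res in fits.items():
            assert res.converged
            # community slopes are shared across severity classes
            z = ((res.params["pct_college"] - coef.gamma[5])
                 / res.bse["pct_college"])
            assert abs(z) < 4.0

    def test_too_small_stratum_rejected(self, prepared):
        lagged, _, _ = prepared
        tiny = lagged.head(30)
        with pytest.raises(ValueError, match="observations"):
            fit_per_cluster(tiny, "phys_encounters")

    @staticmethod
    def _toy_results(gamma_hs, pi_logit=-40.0):
        """A results object with lambda = 2 * exp(gamma_hs * highschool)."""
        from types import SimpleNamespace
        from equicare.count_model import ZeroInflatedPoissonResults
        k = len(ENCOUNTER_DESIGN_COLUMNS)
        params = np.zeros(k + 1)
        params[0] = pi_logit
        cols = {c: j for j, c in enumerate(ENCOUNTER_DESIGN_COLUMNS)}
        params[1 + cols["const"]] = np.log(2.0)
        params[1 + cols["pct_highschool"]] = gamma_hs
        model = SimpleNamespace(exog=None,
                                exog_names=list(ENCOUNTER_DESIGN_COLUMNS),
                                nobs=8)
        return ZeroInflatedPoissonResults(model, params,
                                          np.zeros((k + 1, k + 1)), 0.0,
                                          True, 0.0, 0)

    @staticmethod
    def _toy_panel():
        n = 8
        return pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
            "cholesterol_lag": 1.0, "glucose_lag": 1.0, "age": 1.0,
            "male": 0, "clinical_cluster": 1, "insurance": 1,
            "population": 1.0, "income": 1.0, "pct_white": 0.0,
            "pct_black": 0.0, "pct_college": 0.0,
            # six lower-quartile patients at 0, two upper at 1
            "pct_highschool": [0.0] * 6 + [1.0] * 2,
        })

    def test_quartile_contrast_closed_form(self):
        """With lam = 2 e^{0.5 HS}, pi = 0 and a unit quartile gap the
        contrast is 2(e^0.5 - 1)."""
        out = encounter_quartile_contrast(self._toy_results(0.5),
                                          self._toy_panel(),
                                          "pct_highschool")
        assert out["contrast"] == pytest.approx(2 * (np.exp(0.5) - 1),
                                                abs=1e-8)

    def test_quartile_contrast_zero_when_gamma_zero(self):
        out = encounter_quartile_contrast(self._toy_results(0.0),
                                          self._toy_panel(),
                                          "pct_highschool")
        assert out["contrast"] == pytest.approx(0.0, abs=1e-12)

    def test_contrast_sign_follows_gamma(self, zip_fit, prepared, truth):
        lagged, _, _ = prepared
        out = encounter_quartile_contrast(zip_fit, lagged, "pct_college")
        assert np.sign(out["contrast"]) == np.sign(
            truth.zip_model_params.gamma[5])


def test_params_container_roundtrip_and_validation():
    p = ZipPoissonParams(beta=np.zeros(5), alpha=np.zeros(3),
                         tau=np.zeros(12), gamma=np.arange(6.0), pi=0.2)
    assert ZipPoissonParams.from_dict(p.to_dict()).to_dict() == p.to_dict()
    assert p.coef_vector().shape == (26,)
    with pytest.raises(ValueError):
        ZipPoissonParams(beta=np.zeros(4), alpha=np.zeros(3),
                         tau=np.zeros(12), gamma=np.zeros(6), pi=0.2)
    with pytest.raises(ValueError):
        ZipPoissonParams(beta=np.zeros(5), alpha=np.zeros(3),
                         tau=np.zeros(12), gamma=np.zeros(6), pi=1.4)
    with pytest.raises(KeyError):
        ZipPoissonParams.from_dict({"beta": [0] * 5})
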