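"""Marginal effects: analytic derivatives, AME aggregation, quartile
stratification and the combined two-model contrast."""

import numpy as np
import pandas as pd
import pytest

from equicare.design import (
    NONREF_TRANSITIONS,
    TRANSITION_DESIGN_COLUMNS,
    TRANSITION_TYPES,
    expand_transition_design,
    transition_natural_frame,
)
from equicare.effects import (
    ame_by_quartile,
    average_marginal_effect,
    combined_contrast,
    marginal_effect_analytic,
)
from equicare.transition_model import (
    GlucoseTransitionModel,
    GlucoseTransitionResults,
    softmax_probs,
)

COL = {c: j for j, c in enumerate(TRANSITION_DESIGN_COLUMNS)}
ROW = {t: i for i, t in enumerate(NONREF_TRANSITIONS)}


def _results_from_alpha(alpha):
    """Wrap a coefficient matrix in a results object without fitting."""
    model = type("M", (), {})()
    model.exog_names = list(TRANSITION_DESIGN_COLUMNS)
    model.exog = None
    model.nobs = 0
    model.k_coef = len(TRANSITION_DESIGN_COLUMNS)
    return GlucoseTransitionResults(model, alpha, np.eye(8 * 21), 0.0,
                                    True, False, 0.0, 0)


def _random_natural(n, rng):
    return pd.DataFrame({
        "phys_encounters": rng.poisson(4.0, n).astype(float),
        "tel_encounters": rng.poisson(3.0, n).astype(float),
        "log_age": np.log(rng.uniform(30, 90, n)),
        "pct_white": rng.uniform(0.2, 0.6, n),
        "pct_black": rng.uniform(0.0, 0.3, n),
        "log_income": np.log(rng.uniform(30000, 90000, n)),
        "pct_highschool": rng.uniform(0.7, 1.0, n),
        "pct_college": rng.uniform(0.05, 0.5, n),
        "patient_id": [f"p{i}" for i in range(n)],
    })


def _finite_difference(alpha, natural, variable, h=1e-6):
    up = natural.copy()
    dn = natural.copy()
    up[variable] = up[variable] + h
    dn[variable] = dn[variable] - h
    Pu = softmax_probs(alpha, expand_transition_design(
        transition_natural_frame(up)).to_numpy(float))
    Pd = softmax_probs(alpha, expand_transition_design(
        transition_natural_frame(dn)).to_numpy(float))
    return (Pu - Pd) / (2 * h)


class TestAnalyticDerivative:
    @pytest.mark.parametrize("variable", ["phys_encounters", "tel_encounters",
                                          "log_age", "pct_highschool"])
    def test_matches_central_finite_differences(self, variable):
        rng = np.random.default_rng(17)
        for _ in range(10):
            alpha = rng.normal(scale=0.2, size=(8, 21))
            natural = _random_natural(5, rng)
            me = marginal_effect_analytic(_results_from_alpha(alpha),
                                          natural, variable).to_numpy()
            fd = _finite_difference(alpha, natural, variable)
            assert np.abs(me - fd).max() < 1e-6

    def test_derivatives_sum_to_zero(self):
        rng = np.random.default_rng(18)
        alpha = rng.normal(scale=0.5, size=(8, 21))
        natural = _random_natural(40, rng)
        me = marginal_effect_analytic(_results_from_alpha(alpha), natural,
                                      "phys_encounters")
        assert np.abs(me.sum(axis=1)).max() < 1e-10

    def test_binary_collapse_matches_logistic_form(self):
        """With all but one non-reference category suppressed, the
        derivative reduces to beta * p * (1 - p)."""
        alpha = np.full((8, 21), 0.0)
        alpha[:, COL["const"]] = -500.0  # suppress 7 categories
        j = ROW["D->P"]
        beta = 0.35
        alpha[j, COL["const"]] = 0.4
        alpha[j, COL["phys_encounters"]] = beta
        rng = np.random.default_rng(19)
        natural = _random_natural(30, rng)
        me = marginal_effect_analytic(_results_from_alpha(alpha), natural,
                                      "phys_encounters")
        X = expand_transition_design(natural).to_numpy(float)
        eta = X @ alpha[j]
        p = 1.0 / (1.0 + np.exp(-eta))
        assert np.abs(me["D->P"].to_numpy() - beta * p * (1 - p)).max() < 1e-8

    def test_level_scale_chain_rule(self):
        rng = np.random.default_rng(20)
        alpha = rng.normal(scale=0.2, size=(8, 21))
        natural = _random_natural(10, rng)
        natural["age"] = np.exp(natural["log_age"])
        log_me = marginal_effect_analytic(_results_from_alpha(alpha),
                                          natural, "log_age").to_numpy()
        lvl_me = marginal_effect_analytic(_results_from_alpha(alpha),
                                          natural, "age").to_numpy()
        assert np.allclose(lvl_me, log_me / natural["age"].to_numpy()[:, None])

    def test_unknown_variable_rejected(self):
        with pytest.raises(KeyError):
            marginal_effect_analytic(_results_from_alpha(np.zeros((8, 21))),
                                     _random_natural(2,
                                                     np.random.default_rng(0)),
                                     "cholesterol")


class TestAME:
    def test_single_observation_equals_pointwise(self):
        rng = np.random.default_rng(21)
        alpha = rng.normal(scale=0.3, size=(8, 21))
        natural = _random_natural(1, rng)
        res = _results_from_alpha(alpha)
        ame = average_marginal_effect(res, natural, "phys_encounters",
                                      bootstrap_reps=0)
        me = marginal_effect_analytic(res, natural, "phys_encounters")
        assert np.allclose(ame["ame"].to_numpy(), me.iloc[0].to_numpy())

    def test_ame_sums_to_zero_with_bootstrap_se(self, transition_fit,
                                                transition_obs):
        tab = average_marginal_effect(transition_fit, transition_obs,
                                      "phys_encounters", bootstrap_reps=60,
                                      seed=5)
        assert abs(tab["ame"].sum()) < 1e-10
        assert (tab["se"] > 0).all()

    def test_signal_detected_for_positive_truth_coefficient(self):
        """With a truth whose only nonzero slope is a positive physical-
        encounter effect on D->P, the fitted AME for that cell is positive
        and clears three bootstrap SEs."""
        from equicare import simulate_transition_observations
        from equicare.transition_model import TransitionParams

        alpha = np.zeros((8, 21))
        alpha[ROW["D->P"], COL["phys_encounters"]] = 0.15
        obs = simulate_transition_observations(TransitionParams(alpha),
                                               10000, seed=41)
        fit = GlucoseTransitionModel.from_transitions(obs).fit()
        tab = average_marginal_effect(fit, obs, "phys_encounters",
                                      bootstrap_reps=100, seed=7)
        assert tab.loc["D->P", "ame"] > 0
        assert tab.loc["D->P", "ame"] / tab.loc["D->P", "se"] > 3

    def test_empty_data_rejected(self, transition_fit, transition_obs):
        with pytest.raises(ValueError):
            average_marginal_effect(transition_fit, transition_obs.iloc[0:0],
                                    "phys_encounters")


class TestQuartileAME:
    def test_uniform_effect_gives_equal_strata(self):
        """When the stratifier carries no coefficient and no interaction,
        stratified AMEs coincide."""
        alpha = np.zeros((8, 21))
        alpha[ROW["D->P"], COL["phys_encounters"]] = 0.3
        rng = np.random.default_rng(23)
        natural = _random_natural(200, rng)
        for c in natural.columns:
            if c not in ("pct_college", "patient_id"):
                natural[c] = natural[c].iloc[0]
        tab = ame_by_quartile(_results_from_alpha(alpha), natural,
                              "phys_encounters", "pct_college")
        assert tab["n_obs"].iloc[[0, 9, 18, 27]].sum() == 200
        piv = tab.pivot(index="transition", columns="stratum", values="ame")
        assert np.allclose(piv.std(axis=1), 0.0, atol=1e-14)

    def test_negative_interaction_gives_decreasing_ame(self):
        alpha = np.zeros((8, 21))
        alpha[ROW["D->P"], COL["phys_encounters"]] = 0.5
        alpha[ROW["D->P"], COL["phys_x_pct_highschool"]] = -0.5
        rng = np.random.default_rng(24)
        natural = _random_natural(400, rng)
        tab = ame_by_quartile(_results_from_alpha(alpha), natural,
                              "phys_encounters", "pct_highschool")
        vals = tab[tab["transition"] == "D->P"].sort_values("stratum")["ame"]
        assert (np.diff(vals.to_numpy()) < 0).all()

    def test_empty_stratum_rejected(self):
        alpha = np.zeros((8, 21))
        rng = np.random.default_rng(25)
        natural = _random_natural(20, rng)
        natural["pct_college"] = 0.3  # no variation: strata 2-4 empty
        with pytest.raises(ValueError, match="stratum"):
            ame_by_quartile(_results_from_alpha(alpha), natural,
                            "phys_encounters", "pct_college")


class TestCombinedContrast:
    def test_hand_chained_toy_case(self):
        """Two-covariate toy: the encounter gap and the probability shifts
        are reproduced by direct evaluation of both formulas."""
        from test_count_model import TestStratifiedAndContrast as T
        zres = T._toy_results(0.5)
        panel = T._toy_panel()
        alpha = np.zeros((8, 21))
        alpha[ROW["P->D"], COL["phys_encounters"]] = 0.25
        tres = _results_from_alpha(alpha)
        natural = _random_natural(4, np.random.default_rng(26))
        out = combined_contrast(zres, tres, panel, natural,
                                "pct_highschool", "phys_encounters")
        delta = 2.0 - 2.0 * np.exp(0.5)  # lower minus upper quartile mean
        assert out["encounter_delta"] == pytest.approx(delta, abs=1e-10)
        X0 = expand_transition_design(
            transition_natural_frame(natural)).to_numpy(float)
        shifted = natural.copy()
        shifted["phys_encounters"] += delta
        X1 = expand_transition_design(
            transition_natural_frame(shifted)).to_numpy(float)
        expected = (softmax_probs(alpha, X1)
                    - softmax_probs(alpha, X0)).mean(axis=0)
        got = np.array([out["transition_deltas"][t] for t in TRANSITION_TYPES])
        assert np.abs(got - expected).max() < 1e-10
        assert abs(got.sum()) < 1e-10

    def test_zero_encounter_coefficients_give_zero_deltas(self):
        from test_count_model import TestStratifiedAndContrast as T
        zres = T._toy_results(0.5)
        panel = T._toy_panel()
        alpha = np.zeros((8, 21))
        alpha[:, COL["const"]] = np.linspace(-1, 1, 8)
        alpha[:, COL["pct_white"]] = 0.4  # no encounter terms anywhere
        tres = _results_from_alpha(alpha)
        natural = _random_natural(6, np.random.default_rng(27))
        out = combined_contrast(zres, tres, panel, natural,
                                "pct_highschool", "phys_encounters")
        assert max(abs(v) for v in out["transition_deltas"].values()) == 0.0

    def test_zero_encounter_delta_gives_zero_deltas(self):
        from test_count_model import TestStratifiedAndContrast as T
        zres = T._toy_results(0.0)  # flat rate: quartile gap is zero
        panel = T._toy_panel()
        alpha = np.random.default_rng(28).normal(scale=0.3, size=(8, 21))
        tres = _results_from_alpha(alpha)
        natural = _random_natural(6, np.random.default_rng(29))
        out = combined_contrast(zres, tres, panel, natural,
                                "pct_highschool", "phys_encounters")
        assert out["encounter_delta"] == pytest.approx(0.0, abs=1e-12)
        assert max(abs(v) for v in out["transition_deltas"].values()) < 1e-12

    def test_requires_converged_fits(self, transition_obs):
        from test_count_model import TestStratifiedAndContrast as T
        zres = T._toy_results(0.5)
        model = GlucoseTransitionModel.from_transitions(transition_obs)
        bad = GlucoseTransitionResults(model, np.zeros((8, 21)),
                                       np.eye(8 * 21), 0.0, False, False,
                                       1.0, 0)
        with pytest.raises(ValueError, match="converged"):
            combined_contrast(zres, bad, T._toy_panel(),
                              transition_obs, "pct_highschool")
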