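import numpy as np
import pandas as pd
import pytest

from melsbb.cohort import CohortConfig, DropoutMechanism, generate_cohort, \
    paper_default_truth
from melsbb.design import ModelSpec, build_design
from melsbb.distributions import BetaBinomialParams, moments
from melsbb.inference import PosteriorDraws, fit_map_laplace
from melsbb.model import FixedEffects, RandomEffectsSpec
from melsbb.report import baseline_table, mean_sd_summary
from melsbb.results import (age_curve, or_table, predicted_score_distribution,
                            theta_table)


def _const_draws(beta_p_vals, beta_t_vals, names_p, names_t, n=50):
    S = n
    return PosteriorDraws(
        beta_p=np.tile(beta_p_vals, (S, 1)).astype(float),
        beta_theta=np.tile(beta_t_vals, (S, 1)).astype(float),
        sd=np.ones((S, 3)), corr=np.zeros((S, 3)),
        effects=None, chain=np.zeros(S, dtype=int),
        colnames_p=list(names_p), colnames_theta=list(names_t))


class TestOrTable:
    def test_constant_log2_gives_or_two(self):
        d = _const_draws([0.0, np.log(2)], [0.0],
                         ["intercept", "female"], ["intercept"])
        tab = or_table(d)
        row = tab.set_index("term").loc["female"]
        assert row["estimate"] == pytest.approx(2.0)
        assert row["ci_lo"] == pytest.approx(2.0)
        assert row["ci_hi"] == pytest.approx(2.0)

    def test_negative_coefficient_below_one(self):
        d = _const_draws([0.0, -0.5], [0.0],
                         ["intercept", "adl_between"], ["intercept"])
        assert or_table(d).iloc[0]["estimate"] < 1.0

    def test_spline_terms_excluded(self):
        d = _const_draws([0.0, 1.0, 1.0, 0.3], [0.0],
                         ["intercept", "age_dec", "age_rcs1", "female"],
                         ["intercept"])
        assert list(or_table(d)["term"]) == ["female"]

    def test_recovers_study_female_or(self, midsize_fit):
        *_, draws = midsize_fit
        tab = or_table(draws).set_index("term")
        assert tab.loc["female", "estimate"] == pytest.approx(1.24, abs=0.15)


class TestThetaTable:
    def test_zero_draws_zero_effects(self):
        d = _const_draws([0.0], [0.0, 0.0, 0.0],
                         ["intercept"], ["intercept", "age_dec", "female"])
        tab = theta_table(d)
        assert (tab["estimate"] == 0.0).all()
        assert (tab["variance_ratio"] == 1.0).all()

    def test_negative_effect_means_more_variance(self):
        d = _const_draws([0.0], [2.0, -1.5],
                         ["intercept"], ["intercept", "age_dec"])
        tab = theta_table(d).set_index("term")
        est = tab.loc["age_dec", "estimate"]
        assert est < 0
        _, v_ref = moments(BetaBinomialParams(0.5, np.exp(2.0), 20))
        _, v_old = moments(BetaBinomialParams(0.5, np.exp(2.0 + est), 20))
        assert v_old > v_ref

    def test_recovers_study_age_effect(self, midsize_fit):
        *_, draws = midsize_fit
        tab = theta_table(draws).set_index("term")
        assert tab.loc["age_dec", "estimate"] == pytest.approx(-2.25, abs=0.9)


class TestAgeCurve:
    KNOTS = np.array([-0.7, -0.2, 0.3, 1.2])

    def test_zero_coefficients_flat_at_half(self):
        names = ["intercept", "age_dec", "age_rcs1", "age_rcs2", "female"]
        d = _const_draws([0.0] * 5, [0.0], names, ["intercept"])
        curve = age_curve(d, self.KNOTS, np.linspace(68, 85, 10))
        np.testing.assert_allclose(curve["p_mean"], 0.5, atol=1e-12)
        np.testing.assert_allclose(curve["p_lo"], 0.5, atol=1e-12)

    def test_extrapolation_warns(self):
        names = ["intercept", "age_dec", "age_rcs1", "age_rcs2"]
        d = _const_draws([0.0] * 4, [0.0], names, ["intercept"])
        with pytest.warns(UserWarning, match="knot span"):
            age_curve(d, self.KNOTS, [60.0, 95.0])

    def test_steepening_decline_recovered(self, midsize_fit):
        """The fitted curve drops faster over 80-90 than over 65-75."""
        panel, truth, design, draws = midsize_fit
        curve = age_curve(draws, design.knots, [65.0, 75.0, 80.0, 90.0])
        p = curve.set_index("age")["p_mean"]
        early_drop = p[65.0] - p[75.0]
        late_drop = p[80.0] - p[90.0]
        assert late_drop > early_drop > 0

    def test_interval_narrows_with_sample_size(self, midsize_fit):
        panel_small, truth_small = generate_cohort(
            CohortConfig(n_persons=100, seed=42,
                         dropout=DropoutMechanism(kind="mcar", rate=0.21)))
        d_small = build_design(panel_small, ModelSpec(
            n_knots=4, knots=tuple(truth_small.knots)))
        draws_small = fit_map_laplace(d_small, n_draws=400, seed=0,
                                      store_effects=False)
        *_, d_big, draws_big = midsize_fit
        grid = np.linspace(68, 84, 9)
        w_small = age_curve(draws_small, d_small.knots, grid)
        w_big = age_curve(draws_big, d_big.knots, grid)
        width_small = (w_small["p_hi"] - w_small["p_lo"]).mean()
        width_big = (w_big["p_hi"] - w_big["p_lo"]).mean()
        assert width_big < width_small


class TestScoreDistribution:
    def test_uniform_case_flat(self):
        dist = predicted_score_distribution(0.5, 2.0, 20)
        np.testing.assert_allclose(dist["probability"], 1 / 21, atol=1e-12)

    def test_high_theta_concentrates_at_mean(self):
        dist = predicted_score_distribution(0.5, 50.0, 20)
        probs = dist["probability"].to_numpy()
        assert probs.argmax() == 10
        assert probs[10] > 5 * probs[0]

    def test_low_theta_puts_mass_at_extremes(self):
        dist = predicted_score_distribution(0.5, 0.5, 20)
        probs = dist["probability"].to_numpy()
        assert probs[0] > probs[10]
        assert probs[20] > probs[10]


class TestMeanSdSummary:
    def test_identical_scores_zero_sd(self, toy_panel):
        panel = toy_panel.copy()
        panel.loc[panel.person_id == 1, "score"] = 10
        summ = mean_sd_summary(panel).set_index("person_id")
        assert summ.loc[1, "mean_score"] == 10
        assert summ.loc[1, "sd_score"] == 0.0

    def test_single_observation_person_excluded(self, toy_panel):
        summ = mean_sd_summary(toy_panel)
        assert 2 not in summ["person_id"].values
        assert set(summ["person_id"]) == {1, 3}

    def test_floor_ceiling_inverted_u(self):
        """Cohort with person means spanning the score range: SD is lower at
        extreme means (negative quadratic coefficient)."""
        def spread_truth(knots, cp, ct):
            fe, _ = paper_default_truth(knots, cp, ct)
            re = RandomEffectsSpec(2.0, 0.05, 0.3, corr=np.eye(3))
            beta_t = fe.beta_theta.copy()
            beta_t[0] = 2.0  # moderate dispersion so floors/ceilings bind
            return FixedEffects(fe.beta_p, beta_t), re

        cfg = CohortConfig(n_persons=1500, seed=13,
                           dropout=DropoutMechanism(kind="none"))
        panel, _ = generate_cohort(cfg, truth=spread_truth)
        summ = mean_sd_summary(panel)
        x = summ["mean_score"].to_numpy()
        y = summ["sd_score"].to_numpy()
        coefs = np.polyfit(x, y, 2)
        assert coefs[0] < 0


class TestBaselineTable:
    def test_partition_and_marginals(self):
        cfg = CohortConfig(n_persons=4000, seed=31)
        panel, _ = generate_cohort(cfg)
        tab = baseline_table(panel)
        assert tab.loc["n", "all"] == 4000
        assert tab.loc["n", "completers"] + tab.loc["n", "non_completers"] == 4000
        assert tab.loc["female_pct", "all"] == pytest.approx(54.5, abs=3.0)
        # non-completers older at baseline under covariate-dependent dropout
        assert tab.loc["age_mean", "non_completers"] > tab.loc["age_mean", "completers"]

    def test_single_person_panel_valid(self, toy_panel):
        tab = baseline_table(toy_panel[toy_panel.person_id == 2])
        assert tab.loc["n", "all"] == 1
        assert np.isnan(tab.loc["score_sd", "all"])


class TestEffectTableInvariants:
    def test_validate_rejects_bad_interval(self):
        from melsbb.results import EffectTable
        tab = EffectTable([{"term": "x", "estimate": 1.0, "ci_lo": 2.0,
                            "ci_hi": 3.0, "scale": "log-theta"}])
        with pytest.raises(ValueError):
            tab.validate()

    def test_fit_tables_satisfy_invariants(self, midsize_fit):
        *_, draws = midsize_fit
        for tab in (or_table(draws), theta_table(draws)):
            assert (tab["ci_lo"] <= tab["estimate"]).all()
            assert (tab["estimate"] <= tab["ci_hi"]).all()
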