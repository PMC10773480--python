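import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from melsbb.design import ModelSpec, build_design
from melsbb.distributions import BetaBinomialParams, log_pmf, moments, pmf_oracle
from melsbb.model import (FixedEffects, JointPosterior, PriorSpec,
                          RandomEffectsSpec, joint_log_density,
                          linear_predictor_p, linear_predictor_theta,
                          pointwise_loglik, simulate_from_model)
from melsbb.inference import PosteriorDraws

from conftest import make_toy_panel


def _identity_re(sd=(1.0, 1.0, 1.0)):
    return RandomEffectsSpec(*sd, corr=np.eye(3))


class TestLinearPredictors:
    def test_all_zero_gives_half(self):
        eta = linear_predictor_p(np.zeros(4), FixedEffects(np.zeros(4), np.zeros(2)),
                                 (0.0, 0.0), z_age=0.3)
        assert expit(eta) == 0.5

    def test_random_intercept_shifts_odds(self):
        fe = FixedEffects(np.zeros(1), np.zeros(1))
        eta = linear_predictor_p(np.array([1.0]), fe, (np.log(3), 0.0), z_age=0.0)
        assert expit(eta) == pytest.approx(0.75)

    def test_slope_vanishes_at_centring_age(self):
        fe = FixedEffects(np.zeros(2), np.zeros(1))
        eta = linear_predictor_p(np.zeros(2), fe, (0.0, 5.0), z_age=0.0)
        assert eta == 0.0

    def test_theta_decade_effect(self):
        # one decade above the centring age with the study's age coefficient
        fe = FixedEffects(np.zeros(1), np.array([-2.25]))
        eta = linear_predictor_theta(np.array([1.0]), fe, v0=0.0)
        assert eta == pytest.approx(-2.25)
        assert np.exp(eta) == pytest.approx(np.exp(-2.25))

    def test_all_zero_theta_gives_one(self):
        fe = FixedEffects(np.zeros(1), np.zeros(3))
        assert np.exp(linear_predictor_theta(np.zeros(3), fe, 0.0)) == 1.0

    def test_negative_v0_raises_variance(self):
        base = np.exp(linear_predictor_theta(np.zeros(1),
                                             FixedEffects([0.0], [0.0]), 0.0))
        low = np.exp(linear_predictor_theta(np.zeros(1),
                                            FixedEffects([0.0], [0.0]), -1.5))
        _, v_base = moments(BetaBinomialParams(0.4, base, 20))
        _, v_low = moments(BetaBinomialParams(0.4, low, 20))
        assert v_low > v_base

    def test_dimension_mismatch(self):
        fe = FixedEffects(np.zeros(3), np.zeros(2))
        with pytest.raises(ValueError):
            linear_predictor_p(np.zeros(4), fe, (0, 0), 0.0)


class TestJointLogDensity:
    def _single_obs_design(self, score):
        panel = pd.DataFrame([dict(
            person_id=1, wave=1, age_years=74.2, year_turned_65=1993,
            sex="male", education="none", adl_count=0, test_issue=0,
            score=score, n_trials=20)])
        return build_design(panel, ModelSpec(n_knots=0))

    def test_reduces_to_core_pmf(self):
        d = self._single_obs_design(score=13)
        fe = FixedEffects(np.zeros(d.X_p.shape[1]), np.zeros(d.X_theta.shape[1]))
        re = _identity_re()
        effects = np.zeros((1, 3))
        val = joint_log_density(d, fe, re, effects, include_priors=False)
        expected = log_pmf(13, BetaBinomialParams(0.5, 1.0, 20)) \
            + (-0.5 * 3 * np.log(2 * np.pi))  # standard trivariate normal at 0
        assert val == pytest.approx(float(expected), abs=1e-10)

    def test_duplicated_observations_double_data_term(self, toy_panel):
        d1 = build_design(toy_panel, ModelSpec(n_knots=0))
        doubled = pd.concat([
            toy_panel,
            toy_panel.assign(person_id=toy_panel.person_id + 100)])
        d2 = build_design(doubled, ModelSpec(n_knots=0))
        fe = FixedEffects(np.zeros(d1.X_p.shape[1]), np.zeros(d1.X_theta.shape[1]))
        re = _identity_re()
        e1 = np.zeros((d1.n_persons, 3))
        e2 = np.zeros((d2.n_persons, 3))
        v1 = joint_log_density(d1, fe, re, e1, include_priors=False)
        v2 = joint_log_density(d2, fe, re, e2, include_priors=False)
        re_term = -0.5 * 3 * np.log(2 * np.pi)
        assert v2 - 2 * v1 == pytest.approx(
            d2.n_persons * re_term - 2 * d1.n_persons * re_term, abs=1e-9)

    def test_brute_force_oracle_five_persons(self):
        """Row-by-row recomputation through the quadrature oracle."""
        rng = np.random.default_rng(4)
        rows = []
        for i in range(5):
            base = rng.uniform(66, 86)
            for w in range(1, int(rng.integers(1, 4)) + 1):
                rows.append(dict(
                    person_id=i, wave=w, age_years=base + 2 * (w - 1),
                    year_turned_65=int(2002 - (base - 65)),
                    sex=["male", "female"][int(rng.integers(2))],
                    education=["none", "secondary", "higher"][int(rng.integers(3))],
                    adl_count=int(rng.integers(0, 4)),
                    test_issue=int(rng.integers(0, 2)),
                    score=int(rng.integers(0, 21)), n_trials=20))
        panel = pd.DataFrame(rows)
        d = build_design(panel, ModelSpec(n_knots=3))
        fe = FixedEffects(rng.normal(0, 0.3, d.X_p.shape[1]),
                          rng.normal(0, 0.3, d.X_theta.shape[1])
                          + np.eye(d.X_theta.shape[1])[0] * 2.0)
        re = RandomEffectsSpec(0.5, 0.2, 0.8, corr=np.array([
            [1.0, 0.3, 0.2], [0.3, 1.0, -0.1], [0.2, -0.1, 1.0]]))
        effects = rng.normal(0, 0.4, (d.n_persons, 3))
        val = joint_log_density(d, fe, re, effects, include_priors=False)

        # independent recomputation: per-row quadrature + scipy MVN density
        from scipy.stats import multivariate_normal
        total = 0.0
        for r in range(d.n_obs):
            i = d.person_index[r]
            eta_p = d.X_p[r] @ fe.beta_p + effects[i, 0] + effects[i, 1] * d.z_age[r]
            eta_t = d.X_theta[r] @ fe.beta_theta + effects[i, 2]
            params = BetaBinomialParams(float(expit(eta_p)), float(np.exp(eta_t)),
                                        int(d.n_trials[r]))
            total += np.log(pmf_oracle(int(d.y[r]), params))
        total += multivariate_normal(np.zeros(3), re.cov).logpdf(effects).sum()
        assert val == pytest.approx(total, abs=1e-8)

    def test_non_pd_correlation_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            RandomEffectsSpec(1.0, 1.0, 1.0, corr=bad)


class TestPointwiseLoglik:
    def _draws(self, design, n=2):
        P, Q, I = design.X_p.shape[1], design.X_theta.shape[1], design.n_persons
        return PosteriorDraws(
            beta_p=np.zeros((n, P)), beta_theta=np.full((n, Q), 0.0),
            sd=np.ones((n, 3)), corr=np.zeros((n, 3)),
            effects=np.zeros((n, I, 3)), chain=np.zeros(n, dtype=int),
            colnames_p=design.colnames_p, colnames_theta=design.colnames_theta)

    def test_shape_and_identical_rows(self, toy_panel):
        d = build_design(toy_panel, ModelSpec(n_knots=0))
        ll = pointwise_loglik(self._draws(d), d)
        assert ll.shape == (2, d.n_obs)
        np.testing.assert_array_equal(ll[0], ll[1])

    def test_row_sum_matches_joint_data_term(self, toy_panel):
        d = build_design(toy_panel, ModelSpec(n_knots=0))
        draws = self._draws(d)
        ll = pointwise_loglik(draws, d)
        fe = FixedEffects(draws.beta_p[0], draws.beta_theta[0])
        re = _identity_re()
        dens = joint_log_density(d, fe, re, draws.effects[0],
                                 include_priors=False)
        re_term = -0.5 * 3 * np.log(2 * np.pi) * d.n_persons
        assert ll[0].sum() == pytest.approx(dens - re_term, abs=1e-9)

    def test_missing_effects_error(self, toy_panel):
        d = build_design(toy_panel, ModelSpec(n_knots=0))
        draws = self._draws(d)
        draws.effects = None
        with pytest.raises(ValueError):
            pointwise_loglik(draws, d)


class TestSimulate:
    def test_reproducible(self, small_design):
        d = small_design
        fe = FixedEffects(np.zeros(d.X_p.shape[1]),
                          np.r_[3.0, np.zeros(d.X_theta.shape[1] - 1)])
        re = _identity_re((0.5, 0.1, 0.5))
        s1, e1 = simulate_from_model(d, fe, re, seed=9)
        s2, e2 = simulate_from_model(d, fe, re, seed=9)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(e1, e2)
        assert s1.min() >= 0 and s1.max() <= 20

    def test_zero_re_sds_collapse_to_population_curve(self, small_design):
        d = small_design
        fe = FixedEffects(np.zeros(d.X_p.shape[1]),
                          np.r_[3.0, np.zeros(d.X_theta.shape[1] - 1)])
        re = _identity_re((1e-10, 1e-10, 1e-10))
        _, effects = simulate_from_model(d, fe, re, seed=0)
        assert np.abs(effects).max() < 1e-8

    def test_higher_theta_lowers_within_person_variance(self, small_design):
        """Shifting the dispersion intercept up shrinks score variability."""
        d = small_design
        P, Q = d.X_p.shape[1], d.X_theta.shape[1]
        re = _identity_re((1e-10, 1e-10, 1e-10))
        var = {}
        for label, icpt in (("low", 0.5), ("high", 4.0)):
            fe = FixedEffects(np.zeros(P), np.r_[icpt, np.zeros(Q - 1)])
            scores, _ = simulate_from_model(d, fe, re, seed=3)
            var[label] = scores.var()
        assert var["low"] > var["high"]


class TestJointPosterior:
    @pytest.mark.parametrize("centered", [False, True])
    def test_gradient_matches_finite_differences(self, centered):
        panel = make_toy_panel()
        d = build_design(panel, ModelSpec(n_knots=3))
        post = JointPosterior(d, centered=centered)
        rng = np.random.default_rng(1)
        phi = post.initial_point(rng=rng, jitter=0.25)
        f, g = post.logpost_and_grad(phi)
        assert np.isfinite(f)
        eps = 1e-6
        for k in rng.choice(phi.size, size=12, replace=False):
            e = np.zeros_like(phi)
            e[k] = eps
            num = (post.logpost(phi + e) - post.logpost(phi - e)) / (2 * eps)
            assert g[k] == pytest.approx(num, rel=5e-4, abs=5e-6)

    def test_column_permutation_invariance(self):
        """Permuting design columns together with coefficients leaves the
        density unchanged."""
        panel = make_toy_panel()
        d = build_design(panel, ModelSpec(n_knots=3))
        post = JointPosterior(d)
        rng = np.random.default_rng(2)
        phi = post.initial_point(rng=rng, jitter=0.3)
        f0 = post.logpost(phi)

        perm = rng.permutation(d.X_p.shape[1])
        d2 = build_design(panel, ModelSpec(n_knots=3))
        d2.X_p = d2.X_p[:, perm]
        d2.colnames_p = [d.colnames_p[j] for j in perm]
        post2 = JointPosterior(d2)
        phi2 = phi.copy()
        phi2[:post.P] = phi[:post.P][perm]
        assert post2.logpost(phi2) == pytest.approx(f0, abs=1e-9)

    def test_prior_scale_changes_only_prior_term(self):
        panel = make_toy_panel()
        d = build_design(panel, ModelSpec(n_knots=3))
        rng = np.random.default_rng(3)
        post_a = JointPosterior(d, PriorSpec())
        post_b = JointPosterior(d, PriorSpec(beta_intercept_scale=50.0,
                                             beta_slope_scale=25.0))
        phi = post_a.initial_point(rng=rng, jitter=0.3)
        diff1 = post_b.logpost(phi) - post_a.logpost(phi)
        # analytic prior-term difference for the beta block
        beta = np.concatenate([post_a.unpack(phi)[0], post_a.unpack(phi)[1]])
        expected = -0.5 * np.sum((beta / post_b._beta_scales) ** 2) \
            + 0.5 * np.sum((beta / post_a._beta_scales) ** 2)
        assert diff1 == pytest.approx(expected, abs=1e-9)

        # and the difference is constant in the data-dependent block
        phi2 = phi.copy()
        phi2[-3 * d.n_persons:] += 0.1
        diff2 = post_b.logpost(phi2) - post_a.logpost(phi2)
        assert diff2 == pytest.approx(diff1, abs=1e-9)

    def test_binomial_reduction_with_huge_theta(self, small_design):
        """With the dispersion pinned very high the scores match a plain
        binomial mixed model distributionally."""
        d = small_design
        P, Q = d.X_p.shape[1], d.X_theta.shape[1]
        fe = FixedEffects(np.zeros(P), np.r_[14.0, np.zeros(Q - 1)])
        re = _identity_re((1e-10, 1e-10, 1e-10))
        scores, _ = simulate_from_model(d, fe, re, seed=12)
        rng = np.random.default_rng(12)
        binom = rng.binomial(20, 0.5, size=200_000)
        emp = np.bincount(scores, minlength=21) / scores.size
        ref = np.bincount(binom, minlength=21) / binom.size
        tv = 0.5 * np.abs(emp - ref).sum()
        # MC noise from both samples dominates; distribution identical
        assert tv < 4.0 / np.sqrt(min(scores.size, binom.size))
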