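"""The mixed-effects location-scale beta-binomial model.

Each observed word-recall count y_ij (person i, wave j, n trials) is
beta-binomial with average probability p_ij and dispersion theta_ij:

    logit(p_ij)   = x_ij' beta_p   + u0_i + u1_i * z_age_ij
    log(theta_ij) = w_ij' beta_th  + v0_i

with correlated person-level effects (u0_i, u1_i, v0_i) ~ MVN(0, Sigma),
Sigma = diag(sd) R diag(sd). Low theta means the person's latent success
probabilities are widely dispersed around p — high intraindividual
variability — so covariates in the theta-predictor model who fluctuates,
not just who scores high or low.

The posterior is evaluated on an unconstrained vector in the *non-centred*
parametrization: standardized effects z_i scaled by diag(sd) @ L where L is
the Cholesky factor of R, built from tanh-transformed canonical partial
correlations. Gradients of the joint log posterior are analytic throughout,
which is what makes gradient-based MAP and HMC practical at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln, polygamma, psi

from .design import DesignBundle

__all__ = [
    "FixedEffects",
    "RandomEffectsSpec",
    "PriorSpec",
    "JointPosterior",
    "linear_predictor_p",
    "linear_predictor_theta",
    "joint_log_density",
    "pointwise_loglik",
    "simulate_from_model",
]

LOG_THETA_CLAMP = 27.0  # |log theta| clamp inside likelihood evaluation
_P_EPS = 1e-12


@dataclass(frozen=True)
class FixedEffects:
    """Coefficient vectors aligned to the two design matrices."""

    beta_p: np.ndarray
    beta_theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "beta_p", np.asarray(self.beta_p, dtype=float))
        object.__setattr__(self, "beta_theta", np.asarray(self.beta_theta, dtype=float))
        if not (np.all(np.isfinite(self.beta_p)) and np.all(np.isfinite(self.beta_theta))):
            raise ValueError("fixed effects must be finite")


@dataclass(frozen=True)
class RandomEffectsSpec:
    """Standard deviations and correlation of (u0, u1, v0).

    Order of dimensions: u0 = probability intercept, u1 = probability age
    slope (per decade), v0 = log-dispersion intercept.
    """

    sd_u0: float
    sd_u1: float
    sd_v0: float
    corr: np.ndarray  # 3x3

    def __post_init__(self):
        object.__setattr__(self, "corr", np.asarray(self.corr, dtype=float))
        if min(self.sd_u0, self.sd_u1, self.sd_v0) <= 0:
            raise ValueError("random-effect SDs must be positive")
        R = self.corr
        if R.shape != (3, 3) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("corr must be a symmetric 3x3 matrix with unit diagonal")
        if np.linalg.eigvalsh(R).min() <= 0:
            raise ValueError("corr must be positive definite")

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_u0, self.sd_u1, self.sd_v0])

    @property
    def cov(self) -> np.ndarray:
        s = self.sds
        return self.corr * np.outer(s, s)


@dataclass(frozen=True)
class PriorSpec:
    """Prior settings (all scales > 0).

    Fixed effects get independent normal priors (wider on intercepts);
    random-effect SDs half-Student-t(df, 0, scale); the correlation matrix an
    LKJ prior, implemented exactly through symmetric-beta priors on the
    canonical partial correlations.
    """

    beta_intercept_scale: float = 5.0
    beta_slope_scale: float = 2.5
    sd_scale: float = 2.5
    sd_df: float = 3.0
    lkj_concentration: float = 1.0

    def __post_init__(self):
        for f in ("beta_intercept_scale", "beta_slope_scale", "sd_scale",
                  "sd_df", "lkj_concentration"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


# ---------------------------------------------------------------------------
# correlation transform: raw -> partial correlations -> Cholesky of R
# ---------------------------------------------------------------------------

def _chol_from_raw(raw: np.ndarray):
    """Cholesky factor of the 3x3 correlation matrix from 3 raw parameters.

    raw -> t = tanh(raw) are canonical partial correlations (t1 = r_{u0,u1},
    t2 = r_{u0,v0}, t3 = partial corr of (u1, v0) given u0).
    """
    t1, t2, t3 = np.tanh(raw)
    s1 = np.sqrt(1.0 - t1 * t1)
    s2 = np.sqrt(1.0 - t2 * t2)
    s3 = np.sqrt(1.0 - t3 * t3)
    L = np.array([
        [1.0, 0.0, 0.0],
        [t1, s1, 0.0],
        [t2, t3 * s2, s2 * s3],
    ])
    return L, np.array([t1, t2, t3])


def _chol_raw_grad(G_L: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Chain rule: gradient w.r.t. raw given gradient w.r.t. entries of L."""
    t1, t2, t3 = np.tanh(raw)
    s1 = np.sqrt(1.0 - t1 * t1)
    s2 = np.sqrt(1.0 - t2 * t2)
    s3 = np.sqrt(1.0 - t3 * t3)
    # dL/dt_k, nonzero entries only
    d1 = G_L[1, 0] * 1.0 + G_L[1, 1] * (-t1 / s1)
    d2 = G_L[2, 0] * 1.0 + G_L[2, 1] * (t3 * (-t2 / s2)) + G_L[2, 2] * (-t2 / s2) * s3
    d3 = G_L[2, 1] * s2 + G_L[2, 2] * s2 * (-t3 / s3)
    dt = np.array([d1, d2, d3])
    return dt * (1.0 - np.array([t1, t2, t3]) ** 2)  # tanh jacobian


def corr_from_raw(raw: np.ndarray) -> np.ndarray:
    """Correlations (r_u0u1, r_u0v0, r_u1v0) implied by raw parameters."""
    L, _ = _chol_from_raw(raw)
    R = L @ L.T
    return np.array([R[1, 0], R[2, 0], R[2, 1]])


# ---------------------------------------------------------------------------
# simple per-row predictors (kept as plain functions for clarity/testing)
# ---------------------------------------------------------------------------

def linear_predictor_p(row, fe: FixedEffects, re_effects, z_age: float) -> float:
    """Logit-scale predictor for one design row: x'beta_p + u0 + u1 * z_age."""
    row = np.asarray(row, dtype=float)
    if row.shape[0] != fe.beta_p.shape[0]:
        raise ValueError("design row and beta_p dimensions differ")
    u0, u1 = re_effects
    return float(row @ fe.beta_p + u0 + u1 * z_age)


def linear_predictor_theta(row, fe: FixedEffects, v0: float) -> float:
    """Log-scale dispersion predictor for one design row: w'beta_theta + v0."""
    row = np.asarray(row, dtype=float)
    if row.shape[0] != fe.beta_theta.shape[0]:
        raise ValueError("design row and beta_theta dimensions differ")
    return float(row @ fe.beta_theta + v0)


# ---------------------------------------------------------------------------
# vectorized beta-binomial log likelihood and its derivatives
# ---------------------------------------------------------------------------

def _bb_loglik(y, n, p, theta):
    a = p * theta
    b = (1.0 - p) * theta
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + theta)
        - gammaln(a) - gammaln(b) + gammaln(theta)
    )


def _bb_loglik_grads(y, n, p, theta):
    """Derivatives of the log pmf w.r.t. the logit of p and log of theta."""
    a = p * theta
    b = (1.0 - p) * theta
    da = psi(y + a) - psi(n + theta) - psi(a) + psi(theta)
    db = psi(n - y + b) - psi(n + theta) - psi(b) + psi(theta)
    g_eta_p = theta * (da - db) * p * (1.0 - p)
    g_eta_t = (p * da + (1.0 - p) * db) * theta
    return g_eta_p, g_eta_t


def _bb_loglik_hess(y, n, p, theta):
    """Second derivatives of the log pmf w.r.t. (logit p, log theta).

    Returns (h_pp, h_pt, h_tt) per observation; used by the nested-Laplace
    fitter to build per-person curvature blocks.
    """
    a = p * theta
    b = (1.0 - p) * theta
    q = 1.0 - p
    da = psi(y + a) - psi(n + theta) - psi(a) + psi(theta)
    db = psi(n - y + b) - psi(n + theta) - psi(b) + psi(theta)
    laa = polygamma(1, y + a) - polygamma(1, n + theta) - polygamma(1, a) \
        + polygamma(1, theta)
    lbb = polygamma(1, n - y + b) - polygamma(1, n + theta) - polygamma(1, b) \
        + polygamma(1, theta)
    lab = -polygamma(1, n + theta) + polygamma(1, theta)

    l_p = theta * (da - db)
    l_t = p * da + q * db
    l_pp = theta ** 2 * (laa - 2 * lab + lbb)
    l_pt = (da - db) + theta * (p * laa + q * lab - p * lab - q * lbb)
    l_tt = p ** 2 * laa + 2 * p * q * lab + q ** 2 * lbb

    pq = p * q
    h_pp = l_pp * pq ** 2 + l_p * pq * (1.0 - 2.0 * p)
    h_pt = l_pt * pq * theta
    h_tt = l_tt * theta ** 2 + l_t * theta
    return h_pp, h_pt, h_tt


# ---------------------------------------------------------------------------
# the joint posterior on the unconstrained parameter vector
# ---------------------------------------------------------------------------

class JointPosterior:
    """Log posterior density and gradient for one design + prior spec.

    Unconstrained vector layout:
        [beta_p (P), beta_theta (Q), log_sd (3), corr_raw (3), Z (I*3)]

    With ``centered=False`` (the default, used by HMC) Z holds standardized
    person effects and the actual effects are ``Z @ (S L).T``; with
    ``centered=True`` (used by MAP — the non-centred joint density has no
    interior mode in the SDs) the block holds the effects themselves and the
    trivariate-normal density, including its normalizing determinant,
    enters the posterior explicitly.
    """

    def __init__(self, design: DesignBundle, priors: PriorSpec | None = None,
                 centered: bool = False):
        self.design = design
        self.priors = priors or PriorSpec()
        self.centered = centered
        self.P = design.X_p.shape[1]
        self.Q = design.X_theta.shape[1]
        self.I = design.n_persons
        self.n_params = self.P + self.Q + 6 + 3 * self.I
        self.theta_clamp_events = 0

        p = self.priors
        scales_p = np.full(self.P, p.beta_slope_scale)
        scales_t = np.full(self.Q, p.beta_slope_scale)
        for names, scales in ((design.colnames_p, scales_p),
                              (design.colnames_theta, scales_t)):
            for j, nm in enumerate(names):
                if nm == "intercept":
                    scales[j] = p.beta_intercept_scale
        self._beta_scales = np.concatenate([scales_p, scales_t])
        eta = p.lkj_concentration
        self._pc_beta = np.array([eta + 0.5, eta, eta + 0.5])  # vine exponents, d=3

    # -- packing ------------------------------------------------------------

    def pack(self, beta_p, beta_theta, log_sd, corr_raw, Z) -> np.ndarray:
        return np.concatenate([
            np.asarray(beta_p, float).ravel(),
            np.asarray(beta_theta, float).ravel(),
            np.asarray(log_sd, float).ravel(),
            np.asarray(corr_raw, float).ravel(),
            np.asarray(Z, float).ravel(),
        ])

    def unpack(self, phi: np.ndarray):
        P, Q, I = self.P, self.Q, self.I
        beta_p = phi[:P]
        beta_t = phi[P:P + Q]
        log_sd = phi[P + Q:P + Q + 3]
        raw = phi[P + Q + 3:P + Q + 6]
        Z = phi[P + Q + 6:].reshape(I, 3)
        return beta_p, beta_t, log_sd, raw, Z

    def constrained(self, phi: np.ndarray) -> dict:
        """Interpretable parameter values at one unconstrained point."""
        beta_p, beta_t, log_sd, raw, Z = self.unpack(phi)
        sd = np.exp(log_sd)
        L, _ = _chol_from_raw(raw)
        effects = Z if self.centered else Z @ (sd[:, None] * L).T
        return {
            "beta_p": beta_p.copy(),
            "beta_theta": beta_t.copy(),
            "sd": sd,
            "corr": corr_from_raw(raw),
            "effects": effects,
        }

    def initial_point(self, rng: np.random.Generator | None = None,
                      jitter: float = 0.0) -> np.ndarray:
        """Fixed effects 0 (log-theta intercept at log n for stability),
        SDs 1, correlations 0, standardized effects 0; optional jitter."""
        beta_p = np.zeros(self.P)
        beta_t = np.zeros(self.Q)
        beta_t[self.design.colnames_theta.index("intercept")] = np.log(
            float(np.median(self.design.n_trials)))
        phi = self.pack(beta_p, beta_t, np.zeros(3), np.zeros(3),
                        np.zeros((self.I, 3)))
        if jitter > 0:
            rng = rng or np.random.default_rng()
            phi = phi + jitter * rng.standard_normal(phi.shape)
        return phi

    # -- density ------------------------------------------------------------

    def _predictors(self, beta_p, beta_t, effects):
        d = self.design
        pi = d.person_index
        eta_p = d.X_p @ beta_p + effects[pi, 0] + effects[pi, 1] * d.z_age
        eta_t = d.X_theta @ beta_t + effects[pi, 2]
        return eta_p, eta_t

    def logpost_and_grad(self, phi: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.design
        pr = self.priors
        beta_p, beta_t, log_sd, raw, Z = self.unpack(phi)
        log_sd = np.clip(log_sd, -12.0, 12.0)   # guards line-search overshoot
        raw = np.clip(raw, -12.0, 12.0)
        sd = np.exp(log_sd)
        L, t = _chol_from_raw(raw)
        A = sd[:, None] * L            # Cholesky factor of the effect covariance
        effects = Z if self.centered else Z @ A.T

        eta_p, eta_t = self._predictors(beta_p, beta_t, effects)
        clamped = np.abs(eta_t) > LOG_THETA_CLAMP
        if clamped.any():
            self.theta_clamp_events += int(clamped.sum())
        eta_t_c = np.clip(eta_t, -LOG_THETA_CLAMP, LOG_THETA_CLAMP)
        p = np.clip(expit(eta_p), _P_EPS, 1.0 - _P_EPS)
        theta = np.exp(eta_t_c)

        y, n = d.y, d.n_trials
        ll = _bb_loglik(y, n, p, theta).sum()
        g_eta_p, g_eta_t = _bb_loglik_grads(y, n, p, theta)
        g_eta_t = np.where(clamped, 0.0, g_eta_t)

        # priors shared by both parametrizations
        betas = np.concatenate([beta_p, beta_t])
        lp_beta = -0.5 * np.sum((betas / self._beta_scales) ** 2)
        nu, s = pr.sd_df, pr.sd_scale
        lp_sd = np.sum(-0.5 * (nu + 1.0) * np.log1p(sd ** 2 / (nu * s ** 2)) + log_sd)
        lp_corr = np.sum(self._pc_beta * np.log1p(-t ** 2))
        g_sd_prior = -(nu + 1.0) * sd ** 2 / (nu * s ** 2 + sd ** 2) + 1.0
        g_corr_prior = -2.0 * self._pc_beta * t

        g_beta_p = d.X_p.T @ g_eta_p
        g_beta_t = d.X_theta.T @ g_eta_t
        g_betas = np.concatenate([g_beta_p, g_beta_t]) - betas / self._beta_scales ** 2

        pi = d.person_index
        gE = np.column_stack([
            np.bincount(pi, weights=g_eta_p, minlength=self.I),
            np.bincount(pi, weights=g_eta_p * d.z_age, minlength=self.I),
            np.bincount(pi, weights=g_eta_t, minlength=self.I),
        ])

        if self.centered:
            # effects = Z; trivariate-normal density with its determinant
            from scipy.linalg import solve_triangular
            Minv = solve_triangular(A, np.eye(3), lower=True)
            W = Z @ Minv.T                     # whitened effects
            lp_re = -self.I * (np.sum(log_sd) + np.sum(np.log(np.diag(L)))) \
                - 0.5 * np.sum(W ** 2)
            logpost = ll + lp_beta + lp_sd + lp_corr + lp_re
            g_Z = gE - W @ Minv
            G_M = Minv.T @ (W.T @ W - self.I * np.eye(3))
            G_M = np.tril(G_M)
            g_log_sd = (G_M * A).sum(axis=1) + g_sd_prior
            G_L = sd[:, None] * G_M
            g_raw = _chol_raw_grad(G_L, raw) + g_corr_prior
        else:
            lp_z = -0.5 * np.sum(Z ** 2)
            logpost = ll + lp_beta + lp_sd + lp_corr + lp_z
            g_Z = gE @ A - Z
            g_log_sd = (gE * effects).sum(axis=0) + g_sd_prior
            G_L = sd[:, None] * (gE.T @ Z)
            g_raw = _chol_raw_grad(G_L, raw) + g_corr_prior

        grad = np.concatenate([g_betas[:self.P], g_betas[self.P:],
                               g_log_sd, g_raw, g_Z.ravel()])
        return float(logpost), grad

    def logpost(self, phi: np.ndarray) -> float:
        return self.logpost_and_grad(phi)[0]

    def data_loglik(self, phi: np.ndarray) -> np.ndarray:
        """Per-observation log likelihood at one unconstrained point."""
        c = self.constrained(phi)
        eta_p, eta_t = self._predictors(c["beta_p"], c["beta_theta"], c["effects"])
        p = np.clip(expit(eta_p), _P_EPS, 1.0 - _P_EPS)
        theta = np.exp(np.clip(eta_t, -LOG_THETA_CLAMP, LOG_THETA_CLAMP))
        return _bb_loglik(self.design.y, self.design.n_trials, p, theta)


# ---------------------------------------------------------------------------
# spec-level operations on constrained quantities
# ---------------------------------------------------------------------------

def joint_log_density(design: DesignBundle, fe: FixedEffects,
                      re_spec: RandomEffectsSpec, person_effects: np.ndarray,
                      priors: PriorSpec | None = None,
                      include_priors: bool = True) -> float:
    """Joint log density at given constrained parameter values.

    Sum of the beta-binomial data term at (p_ij, theta_ij), the trivariate
    normal density of the person effects under ``re_spec``, and (optionally)
    the fixed-effect and hyperparameter prior terms.
    """
    from scipy.stats import multivariate_normal

    person_effects = np.asarray(person_effects, dtype=float)
    if person_effects.shape != (design.n_persons, 3):
        raise ValueError("person_effects must have shape (n_persons, 3)")
    if fe.beta_p.shape[0] != design.X_p.shape[1]:
        raise ValueError("beta_p does not match the design")
    if fe.beta_theta.shape[0] != design.X_theta.shape[1]:
        raise ValueError("beta_theta does not match the design")

    pi = design.person_index
    eta_p = design.X_p @ fe.beta_p + person_effects[pi, 0] \
        + person_effects[pi, 1] * design.z_age
    eta_t = design.X_theta @ fe.beta_theta + person_effects[pi, 2]
    p = np.clip(expit(eta_p), _P_EPS, 1.0 - _P_EPS)
    theta = np.exp(np.clip(eta_t, -LOG_THETA_CLAMP, LOG_THETA_CLAMP))
    data_term = _bb_loglik(design.y, design.n_trials, p, theta).sum()

    re_term = multivariate_normal(mean=np.zeros(3), cov=re_spec.cov) \
        .logpdf(person_effects).sum()

    prior_term = 0.0
    if include_priors:
        pr = priors or PriorSpec()
        post = JointPosterior(design, pr)
        betas = np.concatenate([fe.beta_p, fe.beta_theta])
        prior_term += -0.5 * np.sum((betas / post._beta_scales) ** 2)
        nu, s = pr.sd_df, pr.sd_scale
        sds = re_spec.sds
        prior_term += np.sum(-0.5 * (nu + 1.0) * np.log1p(sds ** 2 / (nu * s ** 2)))
    return float(data_term + re_term + prior_term)


def pointwise_loglik(draws, design: DesignBundle) -> np.ndarray:
    """(n_draws, n_obs) conditional log-likelihood matrix for PSIS-LOO.

    Conditional on each draw's sampled person effects — the convention for
    observation-level leave-one-out with hierarchical models.
    """
    if draws.effects is None:
        raise ValueError("draws carry no person effects; refit storing them")
    S = draws.n_draws
    out = np.empty((S, design.n_obs))
    pi = design.person_index
    for s in range(S):
        eff = draws.effects[s]
        eta_p = design.X_p @ draws.beta_p[s] + eff[pi, 0] + eff[pi, 1] * design.z_age
        eta_t = design.X_theta @ draws.beta_theta[s] + eff[pi, 2]
        p = np.clip(expit(eta_p), _P_EPS, 1.0 - _P_EPS)
        theta = np.exp(np.clip(eta_t, -LOG_THETA_CLAMP, LOG_THETA_CLAMP))
        out[s] = _bb_loglik(design.y, design.n_trials, p, theta)
    return out


def simulate_from_model(design: DesignBundle, fe: FixedEffects,
                        re_spec: RandomEffectsSpec, n_trials=None,
                        seed: int = 0):
    """Forward-simulate scores from given parameters.

    Draws person effects from the trivariate normal, forms (p_ij, theta_ij),
    and samples each count by the two-stage beta-then-binomial construction.
    Returns ``(scores, person_effects)`` so recovery tests can compare the
    latent effects too.
    """
    rng = np.random.default_rng(seed)
    I = design.n_persons
    chol = np.linalg.cholesky(re_spec.cov)
    effects = rng.standard_normal((I, 3)) @ chol.T

    pi_idx = design.person_index
    eta_p = design.X_p @ fe.beta_p + effects[pi_idx, 0] + effects[pi_idx, 1] * design.z_age
    eta_t = design.X_theta @ fe.beta_theta + effects[pi_idx, 2]
    p = np.clip(expit(eta_p), _P_EPS, 1.0 - _P_EPS)
    theta = np.exp(np.clip(eta_t, -LOG_THETA_CLAMP, LOG_THETA_CLAMP))

    n = design.n_trials if n_trials is None else np.full(design.n_obs, n_trials)
    latent_pi = rng.beta(p * theta, (1.0 - p) * theta)
    scores = rng.binomial(n, latent_pi)
    return scores, effects
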