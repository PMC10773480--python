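"""Posterior computation: MAP/Laplace, adaptive HMC, and PSIS-LOO.

Two estimation routes share the same :class:`~melsbb.model.JointPosterior`:

``fit_map_laplace``
    Deterministic. L-BFGS on the unconstrained non-centred parametrization
    (person effects optimized jointly with everything else), then a Gaussian
    (Laplace) approximation at the mode whose draws are pushed through the
    constraining transforms. Fast enough for cohort-scale data and for
    repeated model comparison.

``fit_mcmc``
    Full-Bayes Hamiltonian Monte Carlo with dual-averaging step-size
    adaptation and a diagonal mass matrix estimated during warmup. Written
    against the analytic gradient of the joint posterior.

PSIS-LOO delegates the Pareto-smoothing of importance ratios to ``arviz``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .design import DesignBundle
from .model import JointPosterior, PriorSpec, pointwise_loglik

logger = logging.getLogger(__name__)

__all__ = [
    "PosteriorDraws",
    "LooResult",
    "fit_map_laplace",
    "fit_mcmc",
    "psis_loo",
    "compare_models",
]

RHAT_LIMIT = 1.05
PARETO_K_WARN = 0.7


@dataclass
class PosteriorDraws:
    """Labelled posterior draws with convergence diagnostics.

    ``corr`` columns are (r_u0u1, r_u0v0, r_u1v0): probability-intercept ×
    age-slope, probability-intercept × dispersion-intercept, age-slope ×
    dispersion-intercept.
    """

    beta_p: np.ndarray                 # (S, P)
    beta_theta: np.ndarray             # (S, Q)
    sd: np.ndarray                     # (S, 3)
    corr: np.ndarray                   # (S, 3)
    effects: np.ndarray | None         # (S, I, 3) person effects
    chain: np.ndarray                  # (S,) chain index
    colnames_p: list
    colnames_theta: list
    method: str = "map_laplace"
    diagnostics: dict = field(default_factory=dict)

    SD_NAMES = ("sd_u0", "sd_u1", "sd_v0")
    CORR_NAMES = ("corr_u0_u1", "corr_u0_v0", "corr_u1_v0")

    def __post_init__(self):
        for arr in (self.beta_p, self.beta_theta, self.sd, self.corr):
            if not np.all(np.isfinite(arr)):
                raise ValueError("posterior draws contain non-finite values")
        if np.any(self.sd <= 0):
            raise ValueError("SD draws must be positive")
        if np.any(np.abs(self.corr) >= 1):
            raise ValueError("correlation draws must lie in (-1, 1)")

    @property
    def n_draws(self) -> int:
        return self.beta_p.shape[0]

    def param_frame(self) -> pd.DataFrame:
        """All non-person parameters as one draws x parameters frame."""
        cols = {}
        for j, nm in enumerate(self.colnames_p):
            cols[f"p:{nm}"] = self.beta_p[:, j]
        for j, nm in enumerate(self.colnames_theta):
            cols[f"theta:{nm}"] = self.beta_theta[:, j]
        for j, nm in enumerate(self.SD_NAMES):
            cols[nm] = self.sd[:, j]
        for j, nm in enumerate(self.CORR_NAMES):
            cols[nm] = self.corr[:, j]
        return pd.DataFrame(cols)

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and equal-tailed credible interval per parameter."""
        f = self.param_frame()
        lo, hi = 50 * (1 - ci), 50 * (1 + ci)
        out = pd.DataFrame({
            "mean": f.mean(),
            "sd": f.std(ddof=1),
            f"ci_{lo:g}%": f.quantile(lo / 100),
            f"ci_{hi:g}%": f.quantile(hi / 100),
        })
        for key in ("rhat", "ess"):
            if key in self.diagnostics:
                out[key] = pd.Series(self.diagnostics[key]).reindex(out.index)
        return out

    def to_frame(self) -> pd.DataFrame:
        """Draws as a flat frame (one column per parameter) for persistence."""
        f = self.param_frame()
        f.insert(0, "chain", self.chain)
        return f


@dataclass
class LooResult:
    """PSIS-LOO estimate of expected log pointwise predictive density."""

    elpd: float
    se: float
    pareto_k: np.ndarray
    elpd_i: np.ndarray
    p_loo: float = np.nan

    @property
    def n_obs(self) -> int:
        return self.elpd_i.shape[0]

    @property
    def n_bad_k(self) -> int:
        return int((self.pareto_k > PARETO_K_WARN).sum())


# ---------------------------------------------------------------------------
# MAP + Laplace
# ---------------------------------------------------------------------------

def _draws_from_points(post: JointPosterior, points, chain, method, diagnostics,
                       store_effects=True) -> PosteriorDraws:
    S = len(points)
    P, Q, I = post.P, post.Q, post.I
    beta_p = np.empty((S, P)); beta_t = np.empty((S, Q))
    sd = np.empty((S, 3)); corr = np.empty((S, 3))
    eff = np.empty((S, I, 3)) if store_effects else None
    for s, phi in enumerate(points):
        c = post.constrained(phi)
        beta_p[s] = c["beta_p"]; beta_t[s] = c["beta_theta"]
        sd[s] = c["sd"]; corr[s] = c["corr"]
        if store_effects:
            eff[s] = c["effects"]
    return PosteriorDraws(
        beta_p=beta_p, beta_theta=beta_t, sd=sd, corr=corr, effects=eff,
        chain=np.asarray(chain), colnames_p=post.design.colnames_p,
        colnames_theta=post.design.colnames_theta, method=method,
        diagnostics=diagnostics,
    )


class MarginalLaplace:
    """Nested-Laplace posterior approximation.

    The person effects E_i are integrated out by a Newton solve to their
    conditional mode plus a Gaussian (log-determinant) correction — the
    joint posterior of a hierarchical model has no usable interior mode in
    the variance components, so they must be marginalized, not profiled.
    The fixed effects are profiled *inside* the marginal objective by a
    block Newton step (dense fixed-effect block, one 3x3 block per person,
    joined by a Schur complement), so the outer optimization runs over only
    the six variance-component parameters (three log SDs, three
    correlation parameters) with finite-difference gradients. The curvature
    of the non-profiled marginal objective at the optimum provides Gaussian
    posterior draws for all fixed effects and variance components.
    """

    def __init__(self, design: DesignBundle, priors: PriorSpec | None = None):
        from .model import (_bb_loglik, _bb_loglik_grads, _bb_loglik_hess,
                            _chol_from_raw, LOG_THETA_CLAMP, _P_EPS)
        self._bb = (_bb_loglik, _bb_loglik_grads, _bb_loglik_hess)
        self._chol_from_raw = _chol_from_raw
        self._clamp = LOG_THETA_CLAMP
        self._peps = _P_EPS
        self.design = design
        self.post = JointPosterior(design, priors)  # reuses prior bookkeeping
        self.priors = self.post.priors
        self.P, self.Q, self.I = self.post.P, self.post.Q, self.post.I
        self.n_outer = self.P + self.Q + 6
        d = design
        self._zw = d.z_age
        self._pi = d.person_index
        # rows are grouped by person (design construction sorts the panel)
        self._row_starts = np.searchsorted(d.person_index, np.arange(self.I))
        self._E_warm = np.zeros((self.I, 3))
        self._beta_warm = None
        self._prec_beta = 1.0 / self.post._beta_scales ** 2

    # -- parameter handling --------------------------------------------------

    def unpack(self, psi):
        P, Q = self.P, self.Q
        return psi[:P], psi[P:P + Q], psi[P + Q:P + Q + 3], psi[P + Q + 3:]

    def initial_point(self):
        return self.post.initial_point()[:self.n_outer]

    def _sigma_inv(self, tau):
        log_sd = np.clip(tau[:3], -12, 12)
        raw = np.clip(tau[3:], -12, 12)
        sd = np.exp(log_sd)
        L, _ = self._chol_from_raw(raw)
        M = sd[:, None] * L
        Minv = np.linalg.inv(M)
        logdet_sigma = 2.0 * (np.sum(log_sd) + np.sum(np.log(np.diag(L))))
        return Minv.T @ Minv, logdet_sigma

    def _log_prior_beta(self, beta_p, beta_t):
        betas = np.concatenate([beta_p, beta_t])
        return -0.5 * np.sum(betas ** 2 * self._prec_beta)

    def _log_prior_tau(self, tau):
        pr = self.priors
        log_sd = np.clip(tau[:3], -12, 12)
        sd = np.exp(log_sd)
        nu, s = pr.sd_df, pr.sd_scale
        lp = np.sum(-0.5 * (nu + 1) * np.log1p(sd ** 2 / (nu * s ** 2)) + log_sd)
        t = np.tanh(np.clip(tau[3:], -12, 12))
        return lp + np.sum(self.post._pc_beta * np.log1p(-t ** 2))

    # -- row-level quantities ------------------------------------------------

    def _eta(self, beta_p, beta_t, E):
        d = self.design
        pi = self._pi
        eta_p = d.X_p @ beta_p + E[pi, 0] + E[pi, 1] * self._zw
        eta_t = d.X_theta @ beta_t + E[pi, 2]
        return eta_p, eta_t

    def _data_ll(self, eta_p, eta_t):
        from scipy.special import expit
        p = np.clip(expit(eta_p), self._peps, 1 - self._peps)
        theta = np.exp(np.clip(eta_t, -self._clamp, self._clamp))
        return self._bb[0](self.design.y, self.design.n_trials, p, theta), p, theta

    def _seg(self, arr):
        """Per-person sums of a row-aligned array (rows grouped by person)."""
        return np.add.reduceat(arr, self._row_starts, axis=0)

    def _inner_objective(self, beta_p, beta_t, E, Sinv):
        ll = self._data_ll(*self._eta(beta_p, beta_t, E))[0].sum()
        quad = -0.5 * np.einsum("ij,jk,ik->", E, Sinv, E)
        return ll + quad + self._log_prior_beta(beta_p, beta_t)

    def _derivs(self, beta_p, beta_t, E):
        """Row-level first and second derivatives at the current point."""
        eta_p, eta_t = self._eta(beta_p, beta_t, E)
        ll, p, theta = self._data_ll(eta_p, eta_t)
        y, n = self.design.y, self.design.n_trials
        gp, gt = self._bb[1](y, n, p, theta)
        hpp, hpt, htt = self._bb[2](y, n, p, theta)
        return ll, gp, gt, hpp, hpt, htt

    def _person_grad(self, gp, gt, E, Sinv):
        """Per-person gradient (I, 3) of the inner objective."""
        z = self._zw
        return np.column_stack([
            np.bincount(self._pi, weights=gp, minlength=self.I),
            np.bincount(self._pi, weights=gp * z, minlength=self.I),
            np.bincount(self._pi, weights=gt, minlength=self.I),
        ]) - E @ Sinv

    def _person_curv(self, a, b, c, Sinv):
        """Per-person negative-Hessian blocks (I, 3, 3) from row entries
        (a, b, c) = negated second derivatives w.r.t. (eta_p, eta_t)."""
        z = self._zw
        D = np.empty((self.I, 3, 3))
        D[:, 0, 0] = self._seg(a)
        D[:, 0, 1] = D[:, 1, 0] = self._seg(a * z)
        D[:, 1, 1] = self._seg(a * z * z)
        D[:, 0, 2] = D[:, 2, 0] = self._seg(b)
        D[:, 1, 2] = D[:, 2, 1] = self._seg(b * z)
        D[:, 2, 2] = self._seg(c)
        D += Sinv
        return D

    @staticmethod
    def _pd_clip(Dblocks, floor=1e-4):
        """Eigenvalue-floored PD version of a stack of symmetric 3x3 blocks."""
        w, V = np.linalg.eigh(Dblocks)
        w = np.maximum(w, floor)
        return np.einsum("ijk,ik,ilk->ijl", V, w, V), w, V

    @staticmethod
    def _psd_rows(hpp, hpt, htt):
        """Shift each row's 2x2 negative Hessian to PSD.

        The beta-binomial log pmf is not globally concave in (logit p,
        log theta); ridging each observation's 2x2 block by its most
        negative eigenvalue makes every assembled Newton matrix positive
        definite (prior precisions supply strict positivity), so modified
        Newton directions are always ascent directions.
        """
        a, b, c = -hpp, -hpt, -htt
        lam_min = 0.5 * ((a + c) - np.sqrt((a - c) ** 2 + 4.0 * b ** 2))
        delta = np.maximum(0.0, -lam_min)
        return a + delta, b, c + delta

    # -- E-only inner Newton (for Hessian evaluations and draws) -------------

    def _inner_mode(self, beta_p, beta_t, Sinv, tol=1e-9, max_newton=100):
        E = self._E_warm.copy()
        if not np.all(np.isfinite(E)):
            E = np.zeros_like(E)
        f = self._inner_objective(beta_p, beta_t, E, Sinv)
        if not np.isfinite(f):
            E = np.zeros_like(E)
            f = self._inner_objective(beta_p, beta_t, E, Sinv)
        shifted = True
        for _ in range(max_newton):
            _, gp, gt, hpp, hpt, htt = self._derivs(beta_p, beta_t, E)
            G = self._person_grad(gp, gt, E, Sinv)
            gmax = np.max(np.abs(G))
            if gmax < tol:
                break
            # near the optimum switch to the true Hessian for quadratic
            # convergence (the PSD-shifted direction only converges linearly
            # where observations sit in non-concave likelihood regions)
            use_true = gmax < 1e-2 and self._try_true_step
            for attempt in range(2):
                if use_true and attempt == 0:
                    D = self._person_curv(-hpp, -hpt, -htt, Sinv)
                else:
                    a, b, c = self._psd_rows(hpp, hpt, htt)
                    D = self._person_curv(a, b, c, Sinv)
                try:
                    step = np.linalg.solve(D, G[..., None])[..., 0]
                except np.linalg.LinAlgError:
                    continue
                scale, accepted = 1.0, False
                for _half in range(30):
                    E_new = E + scale * step
                    f_new = self._inner_objective(beta_p, beta_t, E_new, Sinv)
                    if np.isfinite(f_new) and f_new >= f - 1e-13 * max(1, abs(f)):
                        accepted = True
                        break
                    scale *= 0.5
                if accepted:
                    break
                if not use_true:
                    break
            if not accepted:
                break
            improved = f_new - f > 1e-13 * max(1.0, abs(f)) or scale == 1.0
            E, f = E_new, f_new
            if not improved:
                break
        _, gp, gt, hpp, hpt, htt = self._derivs(beta_p, beta_t, E)
        D = self._person_curv(-hpp, -hpt, -htt, Sinv)  # true curvature
        self._E_warm = E
        return E, D

    _try_true_step = True

    # -- profile (beta, E) joint Newton --------------------------------------

    def _joint_direction(self, hpp, hpt, htt, G, g_beta, Sinv, shifted):
        """Newton direction for the joint (beta, E) system via the Schur
        complement over the dense fixed-effect block."""
        z = self._zw
        Xp, Xt = self.design.X_p, self.design.X_theta
        K = self.P + self.Q
        if shifted:
            a, b, c = self._psd_rows(hpp, hpt, htt)
        else:
            a, b, c = -hpp, -hpt, -htt
        D = self._person_curv(a, b, c, Sinv)

        B = np.zeros((K, K))
        B[:self.P, :self.P] = (Xp * a[:, None]).T @ Xp
        B[self.P:, self.P:] = (Xt * c[:, None]).T @ Xt
        Bpt = (Xp * b[:, None]).T @ Xt
        B[:self.P, self.P:] = Bpt
        B[self.P:, :self.P] = Bpt.T
        B[np.diag_indices(K)] += self._prec_beta

        C = np.empty((self.I, 3, K))
        C[:, 0, :self.P] = self._seg(Xp * a[:, None])
        C[:, 1, :self.P] = self._seg(Xp * (a * z)[:, None])
        C[:, 2, :self.P] = self._seg(Xp * b[:, None])
        C[:, 0, self.P:] = self._seg(Xt * b[:, None])
        C[:, 1, self.P:] = self._seg(Xt * (b * z)[:, None])
        C[:, 2, self.P:] = self._seg(Xt * c[:, None])

        Dinv = np.linalg.inv(D)
        DinvC = np.einsum("iab,ibk->iak", Dinv, C)
        S = B - np.einsum("iak,ial->kl", C, DinvC)
        DinvG = np.einsum("iab,ib->ia", Dinv, G)
        rhs = g_beta - np.einsum("iak,ia->k", C, DinvG)
        d_beta = np.linalg.solve(S + 1e-10 * np.eye(K), rhs)
        d_E = DinvG - np.einsum("iak,k->ia", DinvC, d_beta)
        return d_beta, d_E

    def beta_precision(self, beta, E, Sinv):
        """Schur-complement precision of the fixed effects given the
        variance components (person effects marginalized within the
        Gaussian approximation), evaluated at (beta, E)."""
        bp, bt = beta[:self.P], beta[self.P:]
        _, gp, gt, hpp, hpt, htt = self._derivs(bp, bt, E)
        z = self._zw
        Xp, Xt = self.design.X_p, self.design.X_theta
        K = self.P + self.Q
        a, b, c = self._psd_rows(hpp, hpt, htt)
        D = self._person_curv(a, b, c, Sinv)
        B = np.zeros((K, K))
        B[:self.P, :self.P] = (Xp * a[:, None]).T @ Xp
        B[self.P:, self.P:] = (Xt * c[:, None]).T @ Xt
        Bpt = (Xp * b[:, None]).T @ Xt
        B[:self.P, self.P:] = Bpt
        B[self.P:, :self.P] = Bpt.T
        B[np.diag_indices(K)] += self._prec_beta
        C = np.empty((self.I, 3, K))
        C[:, 0, :self.P] = self._seg(Xp * a[:, None])
        C[:, 1, :self.P] = self._seg(Xp * (a * z)[:, None])
        C[:, 2, :self.P] = self._seg(Xp * b[:, None])
        C[:, 0, self.P:] = self._seg(Xt * b[:, None])
        C[:, 1, self.P:] = self._seg(Xt * (b * z)[:, None])
        C[:, 2, self.P:] = self._seg(Xt * c[:, None])
        Dinv = np.linalg.inv(D)
        DinvC = np.einsum("iab,ibk->iak", Dinv, C)
        return B - np.einsum("iak,ial->kl", C, DinvC)

    def _profile_newton(self, Sinv, tol=1e-8, max_newton=100):
        d = self.design
        K = self.P + self.Q
        if self._beta_warm is None:
            beta = np.zeros(K)
            beta[self.P + d.colnames_theta.index("intercept")] = np.log(
                float(np.median(d.n_trials)))
        else:
            beta = self._beta_warm.copy()
        E = self._E_warm.copy()
        if not np.all(np.isfinite(E)):
            E = np.zeros_like(E)
        f = self._inner_objective(beta[:self.P], beta[self.P:], E, Sinv)
        if not np.isfinite(f):
            E = np.zeros_like(E)
            beta = np.zeros(K)
            beta[self.P + d.colnames_theta.index("intercept")] = np.log(
                float(np.median(d.n_trials)))
            f = self._inner_objective(beta[:self.P], beta[self.P:], E, Sinv)

        Xp, Xt = d.X_p, d.X_theta
        converged = False
        for _ in range(max_newton):
            bp, bt = beta[:self.P], beta[self.P:]
            _, gp, gt, hpp, hpt, htt = self._derivs(bp, bt, E)
            G = self._person_grad(gp, gt, E, Sinv)
            g_beta = np.concatenate([Xp.T @ gp, Xt.T @ gt]) - beta * self._prec_beta
            gmax = max(np.max(np.abs(G)), np.max(np.abs(g_beta)))
            if gmax < tol:
                converged = True
                break

            use_true = gmax < 1e-2
            accepted = False
            for attempt in range(2):
                shifted = not (use_true and attempt == 0)
                try:
                    d_beta, d_E = self._joint_direction(
                        hpp, hpt, htt, G, g_beta, Sinv, shifted)
                except np.linalg.LinAlgError:
                    continue
                scale = 1.0
                for _half in range(30):
                    beta_new = beta + scale * d_beta
                    E_new = E + scale * d_E
                    f_new = self._inner_objective(beta_new[:self.P],
                                                  beta_new[self.P:], E_new, Sinv)
                    if np.isfinite(f_new) and f_new >= f - 1e-13 * max(1, abs(f)):
                        accepted = True
                        break
                    scale *= 0.5
                if accepted or shifted:
                    break
            if not accepted:
                break
            improved = f_new - f > 1e-13 * max(1.0, abs(f)) or scale == 1.0
            beta, E, f = beta_new, E_new, f_new
            if not improved:
                converged = True  # objective converged to float precision
                break

        bp, bt = beta[:self.P], beta[self.P:]
        _, gp, gt, hpp, hpt, htt = self._derivs(bp, bt, E)
        D = self._person_curv(-hpp, -hpt, -htt, Sinv)  # true curvature
        self._beta_warm = beta
        self._E_warm = E
        return beta, E, D, f, converged

    # -- marginal objectives -------------------------------------------------

    def _laplace_terms(self, Dblocks, logdet_sigma):
        if not np.all(np.isfinite(Dblocks)):
            return None
        w = np.linalg.eigvalsh(Dblocks)
        logdet = np.sum(np.log(np.maximum(w, 1e-6)))
        return -0.5 * self.I * logdet_sigma - 0.5 * logdet

    def value_tau(self, tau):
        """Profile marginal log posterior as a function of the six
        variance-component parameters (fixed effects maximized out)."""
        Sinv, logdet_sigma = self._sigma_inv(tau)
        beta, E, D, f, _ = self._profile_newton(Sinv)
        lap = self._laplace_terms(D, logdet_sigma)
        if lap is None or not np.isfinite(f):
            return -np.inf
        return f + lap + self._log_prior_tau(tau)

    def value(self, psi):
        """Marginal log posterior at full (beta, tau); E integrated out."""
        beta_p, beta_t, log_sd, raw = self.unpack(psi)
        tau = np.concatenate([log_sd, raw])
        Sinv, logdet_sigma = self._sigma_inv(tau)
        E, D = self._inner_mode(beta_p, beta_t, Sinv)
        f = self._inner_objective(beta_p, beta_t, E, Sinv)
        lap = self._laplace_terms(D, logdet_sigma)
        if lap is None or not np.isfinite(f):
            return -np.inf
        return f + lap + self._log_prior_tau(tau)

    def fit(self, maxiter=200, gtol=1e-4, start=None):
        """Maximize the profile marginal posterior over tau, then return the
        full outer mode (profiled fixed effects, optimal tau)."""
        if start is None:
            tau0 = np.zeros(6)
        else:
            start = np.asarray(start, float)
            tau0 = start[self.P + self.Q:] if start.size == self.n_outer else start
        self._beta_warm = None
        self._E_warm = np.zeros((self.I, 3))

        def neg(tau):
            v = self.value_tau(tau)
            return 1e12 if not np.isfinite(v) else -v

        bounds = [(-5.0, 3.0)] * 3 + [(-6.0, 6.0)] * 3
        res = minimize(neg, tau0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter, "maxfun": 50 * maxiter,
                                "gtol": gtol, "ftol": 1e-11,
                                "finite_diff_rel_step": 1e-4},
                       jac=None)
        if not np.isfinite(res.fun) or res.fun >= 1e11:
            raise RuntimeError(f"marginal-Laplace optimization failed: {res.message}")
        tau_hat = res.x
        Sinv, _ = self._sigma_inv(tau_hat)
        beta_hat, E_hat, D_hat, _, converged = self._profile_newton(Sinv)
        res.x_full = np.concatenate([beta_hat, tau_hat])
        res.inner_converged = converged
        return res

    def outer_hessian(self, psi, h=1e-4):
        """Central-difference Hessian of the (non-profiled) marginal log
        posterior over all fixed-effect and variance parameters."""
        D = psi.size
        H = np.empty((D, D))
        f0 = self.value(psi)
        steps = np.eye(D) * h
        fp = np.array([self.value(psi + steps[j]) for j in range(D)])
        fm = np.array([self.value(psi - steps[j]) for j in range(D)])
        for j in range(D):
            H[j, j] = (fp[j] - 2 * f0 + fm[j]) / h ** 2
            for k in range(j + 1, D):
                fpp = self.value(psi + steps[j] + steps[k])
                fmm = self.value(psi - steps[j] - steps[k])
                H[j, k] = H[k, j] = \
                    (fpp + fmm - fp[j] - fm[j] - fp[k] - fm[k] + 2 * f0) / (2 * h ** 2)
        return H

def fit_map_laplace(design: DesignBundle, priors: PriorSpec | None = None,
                    n_draws: int = 1000, seed: int = 0,
                    maxiter: int = 500, gtol: float = 1e-5,
                    store_effects: bool = True, hessian: bool = True,
                    start: np.ndarray | None = None) -> PosteriorDraws:
    """Deterministic fit: marginal posterior mode plus Laplace draws.

    Person effects are integrated out by an inner Newton solve with a
    Gaussian correction (see :class:`MarginalLaplace`); the outer mode over
    fixed effects and variance components is found by L-BFGS. Posterior
    draws are Gaussian at the outer mode (pushed through the constraining
    transforms), with person effects drawn from their conditional Gaussians
    at the mode — an approximation adequate for effect summaries, credible
    intervals and PSIS-LOO screening, and reproducible given ``seed``.

    ``hessian`` selects how much posterior uncertainty the draws carry:
    ``"full"`` (or True, the default) uses the finite-difference curvature
    of the marginal posterior over all fixed effects and variance
    components; ``"beta"`` uses the analytic Schur-complement precision of
    the fixed effects with the variance components pinned at the mode — far
    cheaper and sufficient for elpd-based model screening; ``"none"``
    (or False) pins everything at the mode and varies only person effects.
    """
    hessian = {True: "full", False: "none"}.get(hessian, hessian)
    if hessian not in ("full", "beta", "none"):
        raise ValueError("hessian must be 'full', 'beta' or 'none'")
    ml = MarginalLaplace(design, priors)
    res = ml.fit(maxiter=maxiter, gtol=gtol, start=start)
    mode = res.x_full
    D = mode.size
    K = ml.P + ml.Q
    rng = np.random.default_rng(seed)
    jitter = 0.0

    if hessian == "full":
        H = ml.outer_hessian(mode)
        prec = -H
        for _ in range(10):
            try:
                Lp = np.linalg.cholesky(prec + jitter * np.eye(D))
                break
            except np.linalg.LinAlgError:
                jitter = max(10 * jitter, 1e-8 * np.abs(np.diag(prec)).max())
        else:
            raise RuntimeError("outer Laplace precision is not positive definite")
        z = rng.standard_normal((n_draws, D))
        psis = mode + np.linalg.solve(Lp.T, z.T).T
    else:
        psis = np.tile(mode, (n_draws, 1))

    # conditional person-effect draws at the outer mode
    beta_p, beta_t, log_sd, raw = ml.unpack(mode)
    sd = np.exp(log_sd)
    L, _ = ml._chol_from_raw(raw)
    M = sd[:, None] * L
    Minv = np.linalg.inv(M)
    Sinv = Minv.T @ Minv
    E_hat, D_blocks = ml._inner_mode(beta_p, beta_t, Sinv)
    D_pd, _, _ = ml._pd_clip(D_blocks, floor=1e-6)
    chol_blocks = np.linalg.cholesky(np.linalg.inv(D_pd))

    if hessian == "beta":
        S = ml.beta_precision(mode[:K], E_hat, Sinv)
        Ls = np.linalg.cholesky(0.5 * (S + S.T))
        zb = rng.standard_normal((n_draws, K))
        psis[:, :K] = mode[:K] + np.linalg.solve(Ls.T, zb.T).T

    P, Q, I = ml.P, ml.Q, ml.I
    bp = np.empty((n_draws, P)); bt = np.empty((n_draws, Q))
    sds = np.empty((n_draws, 3)); corr = np.empty((n_draws, 3))
    eff = np.empty((n_draws, I, 3)) if store_effects else None
    from .model import corr_from_raw
    for s in range(n_draws):
        b1, b2, lsd, rw = ml.unpack(psis[s])
        bp[s], bt[s] = b1, b2
        sds[s] = np.exp(np.clip(lsd, -12, 12))
        corr[s] = corr_from_raw(np.clip(rw, -12, 12))
        if store_effects:
            eps = rng.standard_normal((I, 3))
            eff[s] = E_hat + np.einsum("ijk,ik->ij", chol_blocks, eps)

    diagnostics = {
        "method": "map_laplace",
        "converged": bool(res.success),
        "n_iter": int(res.nit),
        "neg_log_marginal": float(res.fun),
        "hessian_jitter": jitter,
        "mode": mode,
    }
    return PosteriorDraws(
        beta_p=bp, beta_theta=bt, sd=sds, corr=corr, effects=eff,
        chain=np.zeros(n_draws, dtype=int), colnames_p=design.colnames_p,
        colnames_theta=design.colnames_theta, method="map_laplace",
        diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# adaptive HMC
# ---------------------------------------------------------------------------

def _leapfrog(post, phi, mom, eps, n_steps, inv_mass):
    f, g = post.logpost_and_grad(phi)
    for _ in range(n_steps):
        mom = mom + 0.5 * eps * g
        phi = phi + eps * inv_mass * mom
        f, g = post.logpost_and_grad(phi)
        if not np.isfinite(f):
            return phi, mom, f, g
        mom = mom + 0.5 * eps * g
    return phi, mom, f, g


class _DualAveraging:
    """Nesterov dual averaging of the log step size toward a target
    acceptance rate."""

    def __init__(self, eps0, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = np.log(10 * eps0)
        self.log_eps_bar = np.log(eps0)
        self.h_bar = 0.0
        self.m = 0
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.eps = eps0

    def update(self, target, alpha):
        self.m += 1
        eta = 1.0 / (self.m + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (target - alpha)
        log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * log_eps + (1 - w) * self.log_eps_bar
        self.eps = float(np.exp(log_eps))

    def restart(self):
        self.mu = np.log(10 * self.eps)
        self.h_bar = 0.0
        self.m = 0


def _warmup_windows(n_warmup):
    """Stan-style schedule: initial step-size phase, doubling covariance
    windows, final step-size phase. Returns mass-window end indices."""
    init = max(int(0.15 * n_warmup), 10)
    term = max(int(0.10 * n_warmup), 10)
    ends, w, pos = [], 25, init
    while pos + w < n_warmup - term:
        pos += w
        ends.append(pos)
        w *= 2
    ends.append(n_warmup - term)
    return ends


def _hmc_chain(post, phi0, n_warmup, n_draws, rng, target_accept, max_leapfrog):
    D = phi0.size
    inv_mass = np.ones(D)
    phi = phi0.copy()
    f, _ = post.logpost_and_grad(phi)
    if not np.isfinite(f):
        raise RuntimeError("non-finite initial density (check the starting point)")

    da = _DualAveraging(0.1)
    window_ends = _warmup_windows(n_warmup)
    welford_n, welford_mean, welford_m2 = 0, np.zeros(D), np.zeros(D)
    in_mass_phase_from = max(int(0.15 * n_warmup), 10)

    draws = np.empty((n_draws, D))
    divergences = 0
    accept_sum = 0.0
    for it in range(n_warmup + n_draws):
        mom = rng.standard_normal(D) / np.sqrt(inv_mass)
        n_steps = int(rng.integers(max(1, max_leapfrog // 2), max_leapfrog + 1))
        f0, _ = post.logpost_and_grad(phi)
        h0 = -f0 + 0.5 * np.sum(inv_mass * mom ** 2)
        phi_new, mom_new, f1, _ = _leapfrog(post, phi, mom, da.eps, n_steps,
                                            inv_mass)
        if np.isfinite(f1):
            h1 = -f1 + 0.5 * np.sum(inv_mass * mom_new ** 2)
            delta_h = h0 - h1
        else:
            delta_h = -np.inf
        if delta_h < -1000 and it >= n_warmup:
            divergences += 1
        alpha = min(1.0, np.exp(min(delta_h, 0.0))) if np.isfinite(delta_h) else 0.0
        if rng.uniform() < alpha:
            phi = phi_new

        if it < n_warmup:
            da.update(target_accept, alpha)
            if it >= in_mass_phase_from:
                welford_n += 1
                delta = phi - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (phi - welford_mean)
            if it + 1 in window_ends:
                if welford_n > 10:
                    var = welford_m2 / (welford_n - 1)
                    # regularized toward unity as Stan does
                    var = (welford_n / (welford_n + 5.0)) * var \
                        + (5.0 / (welford_n + 5.0)) * 1.0
                    inv_mass = np.clip(var, 1e-6, 1e6)
                welford_n, welford_mean, welford_m2 = 0, np.zeros(D), np.zeros(D)
                da.restart()
            if it == n_warmup - 1:
                da.eps = float(np.exp(da.log_eps_bar))
        else:
            accept_sum += alpha
            draws[it - n_warmup] = phi
    return draws, divergences, accept_sum / max(n_draws, 1), da.eps


def fit_mcmc(design: DesignBundle, priors: PriorSpec | None = None,
             chains: int = 4, warmup: int = 1000, draws: int = 1000,
             seed: int = 0, target_accept: float = 0.8,
             max_leapfrog: int = 24, thin: int = 1,
             permissive: bool = False, store_effects: bool = True,
             init_jitter: float = 0.1) -> PosteriorDraws:
    """Full-Bayes fit by adaptive Hamiltonian Monte Carlo.

    Chains are initialized at fixed effects 0, unit SDs, identity
    correlation, jittered per chain; step size adapts by dual averaging to
    ``target_accept`` and a diagonal mass matrix is estimated from the
    middle of warmup. Deterministic given (seed, chains, warmup, draws).
    Raises if any split-R-hat of a fixed effect or variance-component
    parameter exceeds 1.05, unless ``permissive=True``.
    """
    import arviz as az

    post = JointPosterior(design, priors)
    all_draws = []
    chain_ids = []
    div_total = 0
    accepts = []
    root = np.random.SeedSequence(seed)
    for c, ss in enumerate(root.spawn(chains)):
        rng = np.random.default_rng(ss)
        phi0 = post.initial_point(rng=rng, jitter=init_jitter)
        dr, div, acc, eps = _hmc_chain(post, phi0, warmup, draws, rng,
                                       target_accept, max_leapfrog)
        all_draws.append(dr[::thin])
        chain_ids.append(np.full(dr[::thin].shape[0], c, dtype=int))
        div_total += div
        accepts.append(acc)

    pts = np.concatenate(all_draws)
    chain = np.concatenate(chain_ids)
    diagnostics = {
        "method": "hmc",
        "divergences": div_total,
        "accept_rate": float(np.mean(accepts)),
        "chains": chains,
        "warmup": warmup,
        "draws_per_chain": draws,
    }
    out = _draws_from_points(post, list(pts), chain, "hmc", diagnostics,
                             store_effects)

    # split-Rhat / ESS on the interpretable non-person parameters
    f = out.param_frame()
    n_per = len(f) // chains
    data = {name: f[name].to_numpy()[: n_per * chains].reshape(chains, n_per)
            for name in f.columns}
    ds = az.convert_to_dataset(data)
    rhat_ds, ess_ds = az.rhat(ds), az.ess(ds)
    rhat = {name: float(rhat_ds[name].values) for name in f.columns}
    ess = {name: float(ess_ds[name].values) for name in f.columns}
    out.diagnostics["rhat"] = rhat
    out.diagnostics["ess"] = ess
    worst = max(v for v in rhat.values() if np.isfinite(v))
    out.diagnostics["max_rhat"] = worst
    if worst > RHAT_LIMIT and not permissive:
        raise RuntimeError(
            f"MCMC did not converge: max split-Rhat {worst:.3f} > {RHAT_LIMIT} "
            "(rerun with more warmup/draws or permissive=True)")
    if worst > RHAT_LIMIT:
        logger.warning("permissive mode: max split-Rhat %.3f exceeds %.2f",
                       worst, RHAT_LIMIT)
    return out


# ---------------------------------------------------------------------------
# PSIS-LOO and model comparison
# ---------------------------------------------------------------------------

def psis_loo(loglik: np.ndarray) -> LooResult:
    """PSIS-LOO expected log predictive density from a (draws, obs) matrix.

    Importance ratios 1/p(y_i | params_s) are Pareto-smoothed per
    observation (via ``arviz.psislw``); elpd_i is the smoothed importance
    weighted predictive density. Observations with Pareto k > 0.7 are
    counted as unreliable.
    """
    import arviz as az

    loglik = np.asarray(loglik, dtype=float)
    if loglik.ndim != 2 or loglik.shape[0] < 2:
        raise ValueError("need a (n_draws >= 2, n_obs) log-likelihood matrix")
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood matrix contains non-finite values")
    S, N = loglik.shape
    lw, k = az.psislw(-loglik.T)  # (obs, draws) log weights, normalized
    lw = np.asarray(lw); k = np.asarray(k)
    elpd_i = logsumexp(lw + loglik.T, axis=1)
    lpd_i = logsumexp(loglik, axis=0) - np.log(S)
    elpd = float(elpd_i.sum())
    se = float(np.sqrt(N * np.var(elpd_i, ddof=1)))
    return LooResult(elpd=elpd, se=se, pareto_k=k, elpd_i=elpd_i,
                     p_loo=float((lpd_i - elpd_i).sum()))


def loo_from_draws(draws: PosteriorDraws, design: DesignBundle) -> LooResult:
    """Convenience: pointwise conditional log-likelihood then PSIS-LOO."""
    return psis_loo(pointwise_loglik(draws, design))


def compare_models(loos: dict[str, LooResult]) -> pd.DataFrame:
    """Rank candidate models by elpd; flag which are meaningfully preferred.

    ``selected`` marks models whose elpd deficit to the best model is within
    its own difference SE — i.e. a model is only *rejected* (and a more
    complex one "selected" over it) when the elpd difference exceeds its
    standard error, computed from the pointwise elpd differences.
    """
    if len(loos) < 2:
        raise ValueError("need at least two fitted models to compare")
    ns = {name: r.n_obs for name, r in loos.items()}
    if len(set(ns.values())) > 1:
        raise ValueError(f"models were fitted to different data: {ns}")
    best_name = max(loos, key=lambda k: loos[k].elpd)
    best = loos[best_name]
    rows = []
    for name, r in sorted(loos.items(), key=lambda kv: -kv[1].elpd):
        d_i = best.elpd_i - r.elpd_i
        d = float(d_i.sum())
        se_d = float(np.sqrt(r.n_obs * np.var(d_i, ddof=1)))
        rows.append({
            "model": name, "elpd": r.elpd, "se": r.se,
            "elpd_diff": -d, "se_diff": se_d,
            "preferred": name == best_name or d <= se_d,
            "n_bad_k": r.n_bad_k,
        })
    return pd.DataFrame(rows).set_index("model")
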