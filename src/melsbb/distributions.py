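"""Beta-binomial distribution under the mean-dispersion parametrization.

The beta-binomial arises when a count of successes in ``n`` trials has an
underlying success probability that is itself drawn from a beta distribution.
Instead of the usual shape parameters (alpha, beta) we parametrize by the
*average probability* ``p`` (the mean of the beta) and a *dispersion*
parameter ``theta`` (elsewhere written mu/phi/kappa/rho), with

    alpha = p * theta,       beta = (1 - p) * theta.

Small ``theta`` means the underlying probabilities are widely dispersed
around ``p`` (high intraindividual variability when the draws are repeated
test scores from one person); large ``theta`` approaches the plain binomial.
At ``p = 0.5, theta = 2`` the beta is uniform on (0, 1) and the count is
discrete-uniform on ``{0..n}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.special import gammaln

__all__ = [
    "BetaBinomialParams",
    "ScoreSample",
    "to_shape_params",
    "log_pmf",
    "pmf",
    "pmf_oracle",
    "moments",
    "sample",
    "THETA_MIN",
    "THETA_MAX",
]

# dispersion is clamped to this range inside likelihood evaluation to avoid
# overflow of the gamma functions; clamping is counted by the model layer
THETA_MIN = 1e-8
THETA_MAX = 1e12


@dataclass(frozen=True)
class BetaBinomialParams:
    """Mean-dispersion parameters of a beta-binomial distribution.

    Parameters
    ----------
    p : float
        Average probability of success, in the open interval (0, 1).
    theta : float
        Dispersion of the underlying beta distribution (> 0). Lower values
        imply greater spread of the latent probabilities.
    n_trials : int
        Number of Bernoulli trials (>= 1).
    """

    p: float
    theta: float
    n_trials: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"p must lie in (0, 1); got p={self.p}")
        if not self.theta > 0.0:
            raise ValueError(f"theta must be positive; got theta={self.theta}")
        if int(self.n_trials) != self.n_trials or self.n_trials < 1:
            raise ValueError(f"n_trials must be a positive integer; got {self.n_trials}")

    @property
    def alpha(self) -> float:
        return self.p * self.theta

    @property
    def beta(self) -> float:
        return (1.0 - self.p) * self.theta


@dataclass(frozen=True)
class ScoreSample:
    """A reproducible sample of bounded counts."""

    values: np.ndarray
    seed: int
    n_trials: int = 20

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size and (v.min() < 0 or v.max() > self.n_trials):
            raise ValueError("sampled scores fall outside [0, n_trials]")


def to_shape_params(params: BetaBinomialParams) -> tuple[float, float]:
    """Map (p, theta) to the beta shape parameters (alpha, beta).

    The implied beta distribution has mean alpha/(alpha+beta) = p, so the
    average probability is preserved; (p=0.5, theta=2) maps to (1, 1), the
    uniform distribution.
    """
    return params.alpha, params.beta


def _validate_y(y, n_trials):
    y = np.asarray(y)
    if np.any(y < 0) or np.any(y > n_trials):
        raise ValueError(f"count y must lie in [0, {n_trials}]")
    if not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("count y must be integer-valued")
    return y


def log_pmf(y, params: BetaBinomialParams):
    """Log probability mass at count ``y``.

    Computed entirely through log-gamma:

        ln C(n, y) + ln B(y + alpha, n - y + beta) - ln B(alpha, beta)

    which is finite for every valid input.
    """
    y = _validate_y(y, params.n_trials)
    n = params.n_trials
    th = float(np.clip(params.theta, THETA_MIN, THETA_MAX))
    a = params.p * th
    b = (1.0 - params.p) * th
    return (
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + gammaln(y + a) + gammaln(n - y + b) - gammaln(n + a + b)
        - gammaln(a) - gammaln(b) + gammaln(a + b)
    )


def pmf(y, params: BetaBinomialParams):
    """Probability mass at count ``y`` (exp of :func:`log_pmf`)."""
    return np.exp(log_pmf(y, params))


def pmf_oracle(y: int, params: BetaBinomialParams) -> float:
    """Brute-force pmf by adaptive quadrature over the latent probability.

    Integrates C(n,y) * pi**y * (1-pi)**(n-y) against the Beta(alpha, beta)
    density on (0, 1) with ``scipy.integrate.quad``. Deliberately independent
    of :func:`log_pmf` (no shared beta-function code path); accurate to
    ~1e-10, so it serves as a numerical ground truth in tests.
    """
    y_arr = _validate_y(y, params.n_trials)
    if y_arr.ndim != 0:
        raise ValueError("pmf_oracle takes a scalar count")
    yi = int(y_arr)
    n = params.n_trials
    a, b = params.alpha, params.beta
    beta_dist = stats.beta(a, b)

    def integrand(pi: float) -> float:
        return stats.binom.pmf(yi, n, pi) * beta_dist.pdf(pi)

    val, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-12, limit=200)
    return val


def moments(params: BetaBinomialParams) -> tuple[float, float]:
    """Mean and variance of the count.

    mean = n p;  variance = n p (1 - p) (theta + n) / (theta + 1).

    The variance decreases strictly in theta at fixed (n, p), from the
    maximal dispersion toward the binomial variance n p (1 - p).
    """
    n, p, th = params.n_trials, params.p, params.theta
    mean = n * p
    var = n * p * (1.0 - p) * (th + n) / (th + 1.0)
    return mean, var


def sample(params: BetaBinomialParams, count: int, seed: int) -> ScoreSample:
    """Draw counts by the generative two-stage construction.

    Each draw samples a latent probability from Beta(alpha, beta), then the
    count from Binomial(n, pi) — mirroring the data-generating story rather
    than inverting the pmf.
    """
    if int(count) != count or count < 1:
        raise ValueError(f"count must be a positive integer; got {count}")
    rng = np.random.default_rng(seed)
    pi = rng.beta(params.alpha, params.beta, size=count)
    values = rng.binomial(params.n_trials, pi)
    return ScoreSample(values=values, seed=seed, n_trials=params.n_trials)
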