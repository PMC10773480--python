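"""Posterior summaries in the form the study reports them.

Everything here follows transformation-then-summarize: quantities like odds
ratios are computed per posterior draw and then summarized, never by
transforming a summary.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import rcs_basis
from .distributions import BetaBinomialParams, pmf
from .inference import PosteriorDraws, LooResult

__all__ = [
    "EffectTable",
    "or_table",
    "theta_table",
    "age_curve",
    "predicted_score_distribution",
    "MELSResults",
]


class EffectTable(pd.DataFrame):
    """Effect summaries: term, estimate, 95% interval bounds, scale."""

    _metadata: list = []

    @property
    def _constructor(self):
        return EffectTable

    def validate(self) -> "EffectTable":
        if not ((self["ci_lo"] <= self["estimate"] + 1e-12)
                & (self["estimate"] <= self["ci_hi"] + 1e-12)).all():
            raise ValueError("interval bounds do not bracket the estimate")
        orr = self[self["scale"] == "odds-ratio"]
        if (orr[["estimate", "ci_lo", "ci_hi"]] <= 0).any().any():
            raise ValueError("odds ratios must be positive")
        return self


def _summarize(draw_matrix, names, scale, ci=0.95):
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = [{
        "term": nm,
        "estimate": float(np.mean(col)),
        "ci_lo": float(np.percentile(col, lo)),
        "ci_hi": float(np.percentile(col, hi)),
        "scale": scale,
    } for nm, col in zip(names, draw_matrix.T)]
    return EffectTable(rows).validate()


def or_table(draws: PosteriorDraws, ci: float = 0.95) -> EffectTable:
    """Odds ratios for the probability-predictor covariates.

    Each non-spline, non-intercept coefficient is exponentiated draw by
    draw; the age effect is reported through the prediction curve instead
    because individual spline-basis coefficients have no odds-ratio
    reading.
    """
    keep = [j for j, nm in enumerate(draws.colnames_p)
            if nm != "intercept" and not nm.startswith("age_")]
    if not keep:
        raise ValueError("no odds-ratio terms in the probability predictor")
    names = [draws.colnames_p[j] for j in keep]
    return _summarize(np.exp(draws.beta_p[:, keep]), names, "odds-ratio", ci)


def theta_table(draws: PosteriorDraws, ci: float = 0.95,
                variance_ratio: bool = True) -> EffectTable:
    """Log-dispersion effects (negative = more intraindividual variability).

    The optional ``variance_ratio`` column summarizes exp(-coefficient) per
    draw — the approximate multiplicative change in the variance of the
    latent success probabilities per unit of the covariate.
    """
    keep = [j for j, nm in enumerate(draws.colnames_theta) if nm != "intercept"]
    names = [draws.colnames_theta[j] for j in keep]
    tab = _summarize(draws.beta_theta[:, keep], names, "log-theta", ci)
    if variance_ratio:
        tab["variance_ratio"] = [
            float(np.mean(np.exp(-draws.beta_theta[:, j]))) for j in keep]
    return tab


def _profile_row(colnames, profile):
    """Design row at a covariate profile (reference levels, zeros by default)."""
    profile = dict(profile or {})
    row = np.zeros(len(colnames))
    for j, nm in enumerate(colnames):
        if nm == "intercept":
            row[j] = 1.0
        elif nm in profile:
            row[j] = float(profile[nm])
    unknown = set(profile) - set(colnames)
    if unknown:
        raise KeyError(f"profile names not in the design: {sorted(unknown)}")
    return row


def age_curve(draws: PosteriorDraws, knots, age_grid, age_center: float = 74.2,
              covariate_profile: dict | None = None, ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean and interval of the average probability across age.

    All non-age covariates are held at ``covariate_profile`` (default:
    reference categories and centred-zero continuous values); the
    inverse-logit is applied per draw before summarizing.
    """
    ages = np.asarray(age_grid, dtype=float)
    z = (ages - age_center) / 10.0
    knots = np.asarray(knots, dtype=float)
    if z.min() < knots[0] - 1e-9 or z.max() > knots[-1] + 1e-9:
        warnings.warn("age grid extends beyond the fitted knot span; "
                      "the curve is a linear extrapolation there",
                      stacklevel=2)
    basis = rcs_basis(z, knots)
    base_row = _profile_row(draws.colnames_p, covariate_profile)
    X = np.tile(base_row, (len(ages), 1))
    age_cols = [j for j, nm in enumerate(draws.colnames_p)
                if nm == "age_dec" or nm.startswith("age_rcs")]
    if len(age_cols) != basis.shape[1]:
        raise ValueError("knots do not match the fitted age basis")
    X[:, age_cols] = basis
    p_draws = expit(draws.beta_p @ X.T)  # (S, n_ages)
    lo, hi = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    return pd.DataFrame({
        "age": ages,
        "p_mean": p_draws.mean(axis=0),
        "p_lo": np.percentile(p_draws, lo, axis=0),
        "p_hi": np.percentile(p_draws, hi, axis=0),
    })


def predicted_score_distribution(p: float, theta: float,
                                 n_trials: int = 20) -> pd.DataFrame:
    """Exact score pmf at one (p, theta): the shape of expected test scores.

    At p=0.5, theta=2 the pmf is flat at 1/(n+1); theta >> 2 concentrates
    scores near the mean; theta < 2 pushes mass toward the floor and
    ceiling.
    """
    params = BetaBinomialParams(p=p, theta=theta, n_trials=n_trials)
    y = np.arange(n_trials + 1)
    return pd.DataFrame({"score": y, "probability": pmf(y, params)})


class MELSResults:
    """Fit results: posterior draws plus the model they came from.

    Offers the study's reporting surfaces (odds-ratio table, log-dispersion
    table, age prediction curve), generic parameter summaries, and PSIS-LOO
    support. Obtained from :meth:`melsbb.MELSBetaBinomial.fit`.
    """

    def __init__(self, model, draws: PosteriorDraws):
        self.model = model
        self.draws = draws

    # -- generic summaries ---------------------------------------------------

    def summary(self, ci: float = 0.95) -> pd.DataFrame:
        """Posterior mean, sd and credible interval for every fixed effect,
        random-effect SD and correlation."""
        return self.draws.summary(ci=ci)

    @property
    def params(self) -> pd.Series:
        """Posterior means, indexed like :meth:`summary`."""
        return self.draws.param_frame().mean()

    @property
    def diagnostics(self) -> dict:
        return self.draws.diagnostics

    # -- reporting surfaces --------------------------------------------------

    def or_table(self, ci: float = 0.95) -> EffectTable:
        return or_table(self.draws, ci=ci)

    def theta_table(self, ci: float = 0.95, variance_ratio: bool = True) -> EffectTable:
        return theta_table(self.draws, ci=ci, variance_ratio=variance_ratio)

    def age_curve(self, age_grid=None, covariate_profile=None,
                  ci: float = 0.95) -> pd.DataFrame:
        design = self.model.design
        if design.knots is None:
            raise ValueError("the fitted model uses linear age; no spline curve")
        if age_grid is None:
            lo = design.spec.age_center + 10 * design.knots[0]
            hi = design.spec.age_center + 10 * design.knots[-1]
            age_grid = np.linspace(lo, hi, 60)
        return age_curve(self.draws, design.knots, age_grid,
                         age_center=design.spec.age_center,
                         covariate_profile=covariate_profile, ci=ci)

    def predicted_score_distribution(self, p: float, theta: float) -> pd.DataFrame:
        n = int(np.median(self.model.design.n_trials))
        return predicted_score_distribution(p, theta, n_trials=n)

    # -- model fit -----------------------------------------------------------

    def loo(self) -> LooResult:
        """PSIS-LOO expected log predictive density of this fit."""
        from .inference import loo_from_draws
        return loo_from_draws(self.draws, self.model.design)

    def __repr__(self):
        d = self.draws
        return (f"<MELSResults method={d.method!r} draws={d.n_draws} "
                f"persons={self.model.design.n_persons} "
                f"obs={self.model.design.n_obs}>")
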