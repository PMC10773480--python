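"""User-facing model class for the MELS beta-binomial model.

Typical use::

    from melsbb import MELSBetaBinomial, ModelSpec

    model = MELSBetaBinomial.from_dataframe(panel, spec=ModelSpec(n_knots=4))
    res = model.fit()                      # nested-Laplace (deterministic)
    res_mc = model.fit(method="hmc", chains=4, seed=1)   # full Bayes
    res.summary(); res.or_table(); res.theta_table(); res.age_curve()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DesignBundle, ModelSpec, build_design, validate_panel
from .inference import fit_map_laplace, fit_mcmc
from .model import (FixedEffects, PriorSpec, RandomEffectsSpec,
                    JointPosterior, simulate_from_model)
from .results import MELSResults

__all__ = ["MELSBetaBinomial"]


class MELSBetaBinomial:
    """Mixed-effects location-scale beta-binomial model for a panel.

    The bounded count outcome (a word-recall score out of ``n_trials``) is
    beta-binomial with the average probability p modelled on the logit
    scale and the dispersion theta on the log scale, both carrying fixed
    effects of the study covariates, with correlated person-level random
    effects: intercept and age slope for p, intercept for log theta. Low
    theta means high intraindividual variability.

    Parameters
    ----------
    panel : pandas.DataFrame
        Long-format person-wave data with the required study columns.
    spec : ModelSpec, optional
        Age-spline knot count, interactions, centring constants.
    priors : PriorSpec, optional
        Fixed-effect, SD and correlation prior settings.
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec | None = None,
                 priors: PriorSpec | None = None):
        self.panel = validate_panel(panel)
        self.spec = spec or ModelSpec()
        self.priors = priors or PriorSpec()
        self.design: DesignBundle = build_design(self.panel, self.spec)

    @classmethod
    def from_dataframe(cls, panel: pd.DataFrame, spec: ModelSpec | None = None,
                       priors: PriorSpec | None = None) -> "MELSBetaBinomial":
        return cls(panel, spec=spec, priors=priors)

    @classmethod
    def from_csv(cls, path, spec: ModelSpec | None = None,
                 priors: PriorSpec | None = None) -> "MELSBetaBinomial":
        return cls(pd.read_csv(path), spec=spec, priors=priors)

    # -- estimation ----------------------------------------------------------

    def fit(self, method: str = "laplace", **kwargs) -> MELSResults:
        """Estimate the posterior.

        method='laplace' (default): deterministic nested-Laplace fit —
        person effects integrated out by an inner Newton solve, Gaussian
        posterior draws from the curvature at the marginal mode.
        method='hmc': adaptive Hamiltonian Monte Carlo on the full joint
        posterior (non-centred parametrization).
        """
        if method in ("laplace", "map", "map_laplace"):
            draws = fit_map_laplace(self.design, self.priors, **kwargs)
        elif method in ("hmc", "mcmc", "nuts"):
            draws = fit_mcmc(self.design, self.priors, **kwargs)
        else:
            raise ValueError(f"unknown method {method!r}; use 'laplace' or 'hmc'")
        return MELSResults(self, draws)

    # -- generative direction ------------------------------------------------

    def log_density(self, fe: FixedEffects, re_spec: RandomEffectsSpec,
                    person_effects: np.ndarray) -> float:
        """Joint log density (data + random effects + priors) at given
        constrained parameter values."""
        from .model import joint_log_density
        return joint_log_density(self.design, fe, re_spec, person_effects,
                                 self.priors)

    def simulate(self, fe: FixedEffects, re_spec: RandomEffectsSpec,
                 seed: int = 0):
        """Simulate scores (and person effects) from given parameters on
        this model's design."""
        return simulate_from_model(self.design, fe, re_spec, seed=seed)

    def posterior(self, centered: bool = False) -> JointPosterior:
        """The underlying joint posterior object (advanced use)."""
        return JointPosterior(self.design, self.priors, centered=centered)

    def __repr__(self):
        d = self.design
        return (f"<MELSBetaBinomial persons={d.n_persons} obs={d.n_obs} "
                f"knots={self.spec.n_knots}>")
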