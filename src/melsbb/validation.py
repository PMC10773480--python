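"""Truth-recovery and model-selection harnesses on synthetic cohorts.

These are the package's validation experiments: simulate a cohort whose
generating parameters are the study's printed posterior means, refit, and
check that the truth is recovered; and check that PSIS-LOO model comparison
makes the choices the data-generating process warrants (a spline when the
age effect is nonlinear, no interaction when none exists).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (CohortConfig, DropoutMechanism, generate_cohort,
                     paper_default_truth)
from .design import ModelSpec, build_design
from .inference import (compare_models, fit_map_laplace, fit_mcmc, psis_loo)
from .model import pointwise_loglik

__all__ = [
    "HEADLINE_PARAMS",
    "recovery_run",
    "spline_selection_replicate",
    "interaction_selection_replicate",
    "strongly_nonlinear_truth",
]

# the study's 19 headline estimates: 8 odds-ratio terms, 8 log-dispersion
# terms, 3 random-effect correlations
HEADLINE_PARAMS = [
    "p:cohort_dec", "p:female", "p:edu_secondary", "p:edu_higher",
    "p:adl_between", "p:adl_within", "p:issues_between", "p:issues_within",
    "theta:age_dec", "theta:cohort_dec", "theta:female",
    "theta:edu_secondary", "theta:adl_between", "theta:adl_within",
    "theta:issues_between", "theta:issues_within",
    "corr_u0_u1", "corr_u0_v0", "corr_u1_v0",
]


def _truth_series(truth) -> pd.Series:
    vals = truth.named_fixed_effects()
    re = truth.random_effects
    vals.update({
        "sd_u0": re.sd_u0, "sd_u1": re.sd_u1, "sd_v0": re.sd_v0,
        "corr_u0_u1": re.corr[0, 1], "corr_u0_v0": re.corr[0, 2],
        "corr_u1_v0": re.corr[1, 2],
    })
    return pd.Series(vals)


def recovery_run(n_persons: int = 1000, seed: int = 0, method: str = "laplace",
                 n_draws: int = 1000, mcmc_kwargs: dict | None = None):
    """Simulate at the study's printed estimates, refit, compare to truth.

    The cohort uses MCAR dropout calibrated to the study's mean 3.4 observed
    waves. Returns ``(table, draws)`` where ``table`` has the posterior
    summaries with ``truth`` and ``covered`` columns; coverage is judged on
    the equal-tailed 95% credible interval.
    """
    cfg = CohortConfig(n_persons=n_persons, seed=seed,
                       dropout=DropoutMechanism(kind="mcar", rate=0.21))
    panel, truth = generate_cohort(cfg)
    design = build_design(panel, ModelSpec(n_knots=4, knots=tuple(truth.knots)))
    if method == "laplace":
        draws = fit_map_laplace(design, n_draws=n_draws, seed=1,
                                store_effects=False)
    elif method == "hmc":
        kw = dict(chains=2, warmup=500, draws=500, seed=1, permissive=True,
                  store_effects=False)
        kw.update(mcmc_kwargs or {})
        draws = fit_mcmc(design, **kw)
    else:
        raise ValueError(f"unknown method {method!r}")

    table = draws.summary()
    table["truth"] = _truth_series(truth).reindex(table.index)
    lo, hi = table.columns[2], table.columns[3]
    table["covered"] = (table["truth"] >= table[lo]) & (table["truth"] <= table[hi])
    return table, draws


def strongly_nonlinear_truth(knots, colnames_p, colnames_theta):
    """Generating truth whose age effect is nearly flat to ~77 and then
    drops steeply (-1.6 per decade) — a shape a linear age term cannot fit."""

    def profile(z):
        return -0.1 * z - 1.5 * np.log1p(np.exp(4.0 * (z - 0.3))) / 4.0

    return paper_default_truth(knots, colnames_p, colnames_theta,
                               age_profile=profile)


def _loo_for_spec(panel, spec, n_draws=300):
    design = build_design(panel, spec)
    draws = fit_map_laplace(design, n_draws=n_draws, seed=1, hessian="beta")
    return psis_loo(pointwise_loglik(draws, design))


def spline_selection_replicate(seed: int, n_persons: int = 200) -> dict:
    """One replicate of the spline-vs-linear-age comparison under strongly
    nonlinear truth. Returns elpds and whether PSIS-LOO prefers the spline."""
    cfg = CohortConfig(n_persons=n_persons, seed=seed,
                       dropout=DropoutMechanism(kind="mcar", rate=0.21))
    panel, truth = generate_cohort(cfg, truth=strongly_nonlinear_truth)
    ranking = compare_models({
        "spline4": _loo_for_spec(panel, ModelSpec(n_knots=4,
                                                  knots=tuple(truth.knots))),
        "linear": _loo_for_spec(panel, ModelSpec(n_knots=0)),
    })
    return {
        "spline_preferred": ranking.index[0] == "spline4",
        "decisive": bool(not ranking["preferred"].loc["linear"]),
        "elpd_diff": float(ranking["elpd_diff"].min()),
        "se_diff": float(ranking["se_diff"].max()),
    }


def interaction_selection_replicate(seed: int, n_persons: int = 200) -> dict:
    """One replicate of the age-by-sex interaction check under truth with no
    interaction: the richer model should not be selected under the
    elpd-difference-vs-SE decision rule."""
    cfg = CohortConfig(n_persons=n_persons, seed=seed,
                       dropout=DropoutMechanism(kind="mcar", rate=0.21))
    panel, truth = generate_cohort(cfg)
    knots = tuple(truth.knots)
    ranking = compare_models({
        "base": _loo_for_spec(panel, ModelSpec(n_knots=4, knots=knots)),
        "interact": _loo_for_spec(panel, ModelSpec(n_knots=4, knots=knots,
                                                   interactions=("sex",))),
    })
    selected = (ranking.index[0] == "interact"
                and not ranking["preferred"].loc["base"])
    return {
        "interaction_selected": bool(selected),
        "elpd_diff": float(ranking["elpd_diff"].min()),
        "se_diff": float(ranking["se_diff"].max()),
    }
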