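"""Descriptive summaries and figures of a word-recall panel.

These operate on raw panels (no model fit needed): the per-person
mean-vs-SD scatter that motivates modelling intraindividual variability,
and the baseline characteristics table split by completer status.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import validate_panel

__all__ = [
    "mean_sd_summary",
    "baseline_table",
    "plot_mean_sd",
    "plot_age_curve",
    "plot_score_distributions",
]


def mean_sd_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-person mean and SD of the test score (persons with >= 2 waves).

    Sample SD with denominator n-1. Floor and ceiling effects show up here
    as lower SDs at extreme means — the bias that motivates the
    beta-binomial treatment of dispersion.
    """
    panel = validate_panel(panel)
    g = panel.groupby("person_id")["score"]
    out = pd.DataFrame({
        "n_obs": g.size(),
        "mean_score": g.mean(),
        "sd_score": g.std(ddof=1),
    })
    return out[out["n_obs"] >= 2].reset_index()


def _completer_mask(panel: pd.DataFrame) -> pd.Series:
    """Person-level indicator: observed at every wave from entry onward."""
    last_wave = int(panel["wave"].max())
    g = panel.groupby("person_id")["wave"]
    return (g.max() == last_wave) & (g.size() == last_wave - g.min() + 1)


def _summary_block(panel: pd.DataFrame) -> dict:
    base = panel.sort_values("wave").groupby("person_id").first()
    n = len(base)
    out = {"n": n}
    if n == 0:
        return out
    out["age_mean"] = base["age_years"].mean()
    out["age_sd"] = base["age_years"].std(ddof=1) if n > 1 else np.nan
    out["female_pct"] = 100 * (base["sex"] == "female").mean()
    for lvl in ("none", "secondary", "higher"):
        out[f"edu_{lvl}_pct"] = 100 * (base["education"] == lvl).mean()
    for k in range(6):
        out[f"adl_{k}_pct"] = 100 * (base["adl_count"] == k).mean()
    out["issues_pct"] = 100 * (base["test_issue"] == 1).mean()
    out["score_mean"] = base["score"].mean()
    out["score_sd"] = base["score"].std(ddof=1) if n > 1 else np.nan
    return out


def baseline_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics (each person's first included wave), overall
    and by whether the person contributes data to every wave after entry."""
    panel = validate_panel(panel)
    completer = _completer_mask(panel)
    is_comp = panel["person_id"].map(completer)
    blocks = {
        "all": _summary_block(panel),
        "non_completers": _summary_block(panel[~is_comp]),
        "completers": _summary_block(panel[is_comp]),
    }
    return pd.DataFrame(blocks)


# ---------------------------------------------------------------------------
# figures (matplotlib; every function returns the Axes)
# ---------------------------------------------------------------------------

def plot_mean_sd(panel: pd.DataFrame, ax=None, jitter: float = 0.15,
                 seed: int = 0):
    """Scatter of per-person SD against mean score, with light jitter."""
    import matplotlib.pyplot as plt

    summ = mean_sd_summary(panel)
    rng = np.random.default_rng(seed)
    x = summ["mean_score"] + rng.uniform(-jitter, jitter, len(summ))
    y = summ["sd_score"] + rng.uniform(-jitter, jitter, len(summ))
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(x, y, s=6, alpha=0.3, edgecolors="none")
    ax.set_xlabel("mean word recall score")
    ax.set_ylabel("SD of word recall score")
    return ax


def plot_age_curve(curve: pd.DataFrame, ax=None):
    """Average-probability-by-age curve with its credible band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve["age"], curve["p_mean"], color="C0")
    ax.fill_between(curve["age"], curve["p_lo"], curve["p_hi"],
                    color="C0", alpha=0.25, linewidth=0)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("average probability of recall (p)")
    ax.set_ylim(0, 1)
    return ax


def plot_score_distributions(param_grid, n_trials: int = 20, ax=None):
    """Expected score distributions at several (p, theta) values.

    ``param_grid`` is an iterable of (p, theta) pairs; the theta=2, p=0.5
    case is the flat benchmark where every score is equally likely.
    """
    import matplotlib.pyplot as plt

    from .results import predicted_score_distribution

    if ax is None:
        _, ax = plt.subplots()
    for p, theta in param_grid:
        dist = predicted_score_distribution(p, theta, n_trials)
        ax.plot(dist["score"], dist["probability"], marker="o", ms=3,
                label=f"p={p:g}, θ={theta:g}")
    ax.set_xlabel("score")
    ax.set_ylabel("probability")
    ax.legend(fontsize=8)
    return ax
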