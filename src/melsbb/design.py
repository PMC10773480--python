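"""Covariate encodings for the word-recall panel.

Turns a long-format person-wave table into the numeric design matrices the
model uses: centred/decade-scaled age and birth-cohort, a restricted cubic
spline basis for age in the probability predictor, dummy-coded sex and
education with explicit reference levels (male; no qualifications), and the
between/within decomposition of the time-varying covariates (ADL-difficulty
count and the interviewer test-issue indicator) into person-level means and
person-mean-centred deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_CENTER",
    "COHORT_CENTER",
    "HARRELL_QUANTILES",
    "PANEL_COLUMNS",
    "ModelSpec",
    "DesignBundle",
    "validate_panel",
    "read_panel_csv",
    "center_age",
    "center_cohort",
    "select_knots",
    "rcs_basis",
    "within_between",
    "build_design",
]

AGE_CENTER = 74.2     # sample-mean age used for centring, in years
COHORT_CENTER = 1999  # centring year for the year-turned-65 cohort variable

# Harrell's recommended knot placement (outer and interior quantiles per k)
HARRELL_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}

PANEL_COLUMNS = [
    "person_id", "wave", "age_years", "year_turned_65", "sex",
    "education", "adl_count", "test_issue", "score", "n_trials",
]

_SEX_LEVELS = ("male", "female")
_EDU_LEVELS = ("none", "secondary", "higher")


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one candidate model.

    Parameters
    ----------
    n_knots : int
        Number of knots of the restricted cubic spline for age in the
        probability predictor; 0 requests a plain linear age term.
    interactions : tuple of str
        Covariates whose product with (linear, centred) age is added to the
        probability predictor; subset of
        {"sex", "education", "adl", "test_issue"}. Default empty.
    age_center, cohort_center : float
        Centring constants; ages and cohort years enter in decades.
    """

    n_knots: int = 4
    interactions: tuple = ()
    age_center: float = AGE_CENTER
    cohort_center: float = COHORT_CENTER
    knots: tuple | None = None  # explicit knot override, age-decade scale

    def __post_init__(self):
        if self.n_knots not in (0, 3, 4, 5):
            raise ValueError("n_knots must be 0 (linear age) or one of {3,4,5}")
        bad = set(self.interactions) - {"sex", "education", "adl", "test_issue"}
        if bad:
            raise ValueError(f"unknown interaction covariates: {sorted(bad)}")


@dataclass
class DesignBundle:
    """Numeric design matrices induced by a panel and a :class:`ModelSpec`."""

    X_p: np.ndarray
    X_theta: np.ndarray
    z_age: np.ndarray            # centred age in decades, random-slope variable
    y: np.ndarray
    n_trials: np.ndarray
    person_index: np.ndarray     # row -> 0-based person position
    person_ids: np.ndarray       # position -> original id
    colnames_p: list = field(default_factory=list)
    colnames_theta: list = field(default_factory=list)
    knots: np.ndarray | None = None
    spec: ModelSpec | None = None

    @property
    def n_obs(self) -> int:
        return self.X_p.shape[0]

    @property
    def n_persons(self) -> int:
        return len(self.person_ids)

    @property
    def obs_per_person(self) -> np.ndarray:
        return np.bincount(self.person_index, minlength=self.n_persons)


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the panel invariants and drop rows with missing modelled fields.

    Invariants: ages >= 65, scores within [0, n_trials], (person_id, wave)
    unique, year_turned_65 constant within person, known category levels.
    Rows with missing values in any modelled column are dropped with a
    logged count (no imputation).
    """
    missing_cols = [c for c in PANEL_COLUMNS if c not in panel.columns and c != "n_trials"]
    if missing_cols:
        raise ValueError(f"panel is missing required columns: {missing_cols}")
    panel = panel.copy()
    if "n_trials" not in panel.columns:
        panel["n_trials"] = 20

    n0 = len(panel)
    panel = panel.dropna(subset=[c for c in PANEL_COLUMNS])
    if len(panel) < n0:
        logger.info("dropped %d rows with missing modelled fields", n0 - len(panel))
    if panel.empty:
        raise ValueError("panel has no complete rows")

    if (panel["age_years"] < 65).any():
        raise ValueError("panel contains ages below 65")
    if ((panel["score"] < 0) | (panel["score"] > panel["n_trials"])).any():
        raise ValueError("scores fall outside [0, n_trials]")
    if panel.duplicated(subset=["person_id", "wave"]).any():
        raise ValueError("duplicate (person_id, wave) rows")
    if (panel.groupby("person_id")["year_turned_65"].nunique() > 1).any():
        raise ValueError("year_turned_65 varies within person")
    bad_sex = set(panel["sex"].unique()) - set(_SEX_LEVELS)
    if bad_sex:
        raise ValueError(f"unknown sex levels: {sorted(bad_sex)}")
    bad_edu = set(panel["education"].unique()) - set(_EDU_LEVELS)
    if bad_edu:
        raise ValueError(f"unknown education levels: {sorted(bad_edu)}")
    return panel


def read_panel_csv(path) -> pd.DataFrame:
    """Read and validate a long-format panel CSV (header row, UTF-8)."""
    return validate_panel(pd.read_csv(path))


def center_age(age_years, center: float = AGE_CENTER):
    """Centre age on the sample-mean constant and scale to decades."""
    return (np.asarray(age_years, dtype=float) - center) / 10.0


def center_cohort(year_turned_65, center: float = COHORT_CENTER):
    """Centre the year a person turned 65 and scale to decades."""
    return (np.asarray(year_turned_65, dtype=float) - center) / 10.0


def select_knots(values, k: int) -> np.ndarray:
    """Empirical-quantile knots at Harrell's recommended positions."""
    if k not in HARRELL_QUANTILES:
        raise ValueError(f"k must be one of {sorted(HARRELL_QUANTILES)}; got {k}")
    values = np.sort(np.asarray(values, dtype=float))
    knots = np.quantile(values, HARRELL_QUANTILES[k])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("degenerate data: knot locations are not strictly increasing")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis with k-1 columns.

    Column 0 is ``x`` itself; columns 1..k-2 are the truncated-power cubic
    terms constrained so the function is linear beyond the boundary knots,
    normalised by (t_k - t_1)^2 so every column is on the scale of ``x``.
    The basis is continuous with continuous first derivative everywhere.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = len(t)
    if k < 3:
        raise ValueError("need at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ValueError("knots must be strictly increasing")

    def cube(u):
        return np.where(u > 0, u, 0.0) ** 3

    norm = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / (t[-1] - t[-2])
            + cube(x - t[-1]) * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / norm)
    return np.column_stack(cols)


def within_between(person_ids, values) -> tuple[np.ndarray, np.ndarray]:
    """Decompose a time-varying covariate into person means and deviations.

    Returns ``(between, within)`` where ``between`` is each person's mean
    expanded back to rows and ``within = value - between``; their sum
    reconstructs the covariate exactly and the within part sums to zero
    within every person.
    """
    person_ids = np.asarray(person_ids)
    values = np.asarray(values, dtype=float)
    if person_ids.shape[0] != values.shape[0]:
        raise ValueError("person_ids and values must align")
    if person_ids.shape[0] == 0:
        raise ValueError("empty input")
    s = pd.Series(values)
    between = s.groupby(pd.Series(person_ids)).transform("mean").to_numpy()
    return between, values - between


def build_design(panel: pd.DataFrame, spec: ModelSpec | None = None) -> DesignBundle:
    """Build both design matrices from a validated panel.

    Probability-predictor columns, in order: intercept, age spline basis
    (k-1 columns, or one linear column when n_knots=0), cohort decades,
    female, education contrasts (secondary, higher; reference = no
    qualifications), ADL between/within, test-issue between/within, then any
    requested age-interaction columns. The dispersion (log-theta) predictor
    uses the same covariates with a single linear age-decade term.
    Construction is a pure function of (panel, spec).
    """
    spec = spec or ModelSpec()
    panel = validate_panel(panel)
    panel = panel.sort_values(["person_id", "wave"], kind="mergesort").reset_index(drop=True)

    person_ids, person_index = np.unique(panel["person_id"].to_numpy(), return_inverse=True)

    z_age = center_age(panel["age_years"].to_numpy(), spec.age_center)
    cohort = center_cohort(panel["year_turned_65"].to_numpy(), spec.cohort_center)
    female = (panel["sex"].to_numpy() == "female").astype(float)
    edu_sec = (panel["education"].to_numpy() == "secondary").astype(float)
    edu_hi = (panel["education"].to_numpy() == "higher").astype(float)
    adl_b, adl_w = within_between(person_index, panel["adl_count"].to_numpy())
    iss_b, iss_w = within_between(person_index, panel["test_issue"].to_numpy())

    if spec.n_knots == 0:
        age_cols = z_age[:, None]
        age_names = ["age_dec"]
        knots = None
    else:
        if spec.knots is not None:
            knots = np.asarray(spec.knots, dtype=float)
        else:
            knots = select_knots(z_age, spec.n_knots)
        age_cols = rcs_basis(z_age, knots)
        age_names = ["age_dec"] + [f"age_rcs{j}" for j in range(1, age_cols.shape[1])]

    n = len(panel)
    blocks = [np.ones(n), *age_cols.T, cohort, female, edu_sec, edu_hi,
              adl_b, adl_w, iss_b, iss_w]
    names_p = ["intercept", *age_names, "cohort_dec", "female",
               "edu_secondary", "edu_higher", "adl_between", "adl_within",
               "issues_between", "issues_within"]

    inter_vars = {
        "sex": [("female", female)],
        "education": [("edu_secondary", edu_sec), ("edu_higher", edu_hi)],
        "adl": [("adl_between", adl_b), ("adl_within", adl_w)],
        "test_issue": [("issues_between", iss_b), ("issues_within", iss_w)],
    }
    for key in spec.interactions:
        for nm, col in inter_vars[key]:
            blocks.append(z_age * col)
            names_p.append(f"age_dec:{nm}")

    X_p = np.column_stack(blocks)

    X_theta = np.column_stack([
        np.ones(n), z_age, cohort, female, edu_sec, edu_hi,
        adl_b, adl_w, iss_b, iss_w,
    ])
    names_t = ["intercept", "age_dec", "cohort_dec", "female",
               "edu_secondary", "edu_higher", "adl_between", "adl_within",
               "issues_between", "issues_within"]

    return DesignBundle(
        X_p=X_p,
        X_theta=X_theta,
        z_age=z_age,
        y=panel["score"].to_numpy(dtype=int),
        n_trials=panel["n_trials"].to_numpy(dtype=int),
        person_index=person_index,
        person_ids=person_ids,
        colnames_p=names_p,
        colnames_theta=names_t,
        knots=knots,
        spec=spec,
    )
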