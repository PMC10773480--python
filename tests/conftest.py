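import numpy as np
import pandas as pd
import pytest

from melsbb.cohort import CohortConfig, DropoutMechanism, generate_cohort
from melsbb.design import ModelSpec, build_design


def make_toy_panel():
    """Three persons, hand-written rows (printed fixture)."""
    return pd.DataFrame([
        # person 1: two waves, ADL rises 0 -> 2, no test issues
        dict(person_id=1, wave=1, age_years=66.0, year_turned_65=2001,
             sex="male", education="none", adl_count=0, test_issue=0,
             score=12, n_trials=20),
        dict(person_id=1, wave=2, age_years=68.0, year_turned_65=2001,
             sex="male", education="none", adl_count=2, test_issue=0,
             score=9, n_trials=20),
        # person 2: single wave, female, higher education, one test issue
        dict(person_id=2, wave=1, age_years=74.2, year_turned_65=1993,
             sex="female", education="higher", adl_count=1, test_issue=1,
             score=17, n_trials=20),
        # person 3: three waves, secondary education
        dict(person_id=3, wave=1, age_years=80.0, year_turned_65=1987,
             sex="female", education="secondary", adl_count=0, test_issue=0,
             score=7, n_trials=20),
        dict(person_id=3, wave=2, age_years=82.0, year_turned_65=1987,
             sex="female", education="secondary", adl_count=1, test_issue=1,
             score=4, n_trials=20),
        dict(person_id=3, wave=3, age_years=84.0, year_turned_65=1987,
             sex="female", education="secondary", adl_count=1, test_issue=0,
             score=10, n_trials=20),
    ])


@pytest.fixture
def toy_panel():
    return make_toy_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """150-person synthetic cohort with its truth (shared across tests)."""
    cfg = CohortConfig(n_persons=150, seed=7,
                       dropout=DropoutMechanism(kind="mcar", rate=0.21))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_design(small_cohort):
    panel, truth = small_cohort
    spec = ModelSpec(n_knots=4, knots=tuple(truth.knots))
    return build_design(panel, spec)


@pytest.fixture(scope="session")
def midsize_fit():
    """One 500-person nested-Laplace fit reused by reporting tests."""
    from melsbb.inference import fit_map_laplace

    cfg = CohortConfig(n_persons=500, seed=42,
                       dropout=DropoutMechanism(kind="mcar", rate=0.21))
    panel, truth = generate_cohort(cfg)
    design = build_design(panel, ModelSpec(n_knots=4, knots=tuple(truth.knots)))
    draws = fit_map_laplace(design, n_draws=800, seed=3)
    return panel, truth, design, draws
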