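import numpy as np
import pandas as pd
import pytest

from netgradient.cohort import ScenarioConfig, generate_cohort
from netgradient.lifetables import LifeTable, make_gompertz_lifetable


@pytest.fixture(scope="session")
def lifetable():
    return make_gompertz_lifetable()


@pytest.fixture(scope="session")
def zero_lifetable(lifetable):
    """A life table with hP identically zero (net = overall survival)."""
    return LifeTable(np.zeros_like(lifetable.rates), lifetable.age_min,
                     lifetable.year_min, lifetable.sexes, lifetable.regions)


@pytest.fixture(scope="session")
def exponential_cohort(zero_lifetable):
    """Exponential excess hazard, no background mortality, no LTF."""
    cfg = ScenarioConfig(
        n_subjects=1000, seed=5, effect_kind="null",
        baseline_excess_hazard={"dist": "weibull", "shape": 1.0, "scale": 5.0,
                                "log_age_slope": 0.0},
        loss_to_followup_rate=0.0)
    return generate_cohort(cfg, zero_lifetable)


@pytest.fixture(scope="session")
def proportional_cohort(lifetable):
    """Moderate proportional deprivation effect on the excess hazard."""
    cfg = ScenarioConfig(n_subjects=800, seed=11, effect_kind="proportional",
                         beta_edi=0.024)
    return generate_cohort(cfg, lifetable)


@pytest.fixture(scope="session")
def m1_fit(proportional_cohort, lifetable):
    """A converged M1 fit shared across tests (LAML-selected smoothing)."""
    from netgradient.hazard_model import ModelSpec, optimize_laml

    spec = ModelSpec.from_cohort("M1", proportional_cohort.df, n_quad=12)
    return optimize_laml(spec, proportional_cohort.df, lifetable,
                         starts=(1.0,), outer_maxiter=5)


@pytest.fixture(scope="session")
def tiny_cohort_df():
    """Three handmade records for exact-arithmetic checks."""
    return pd.DataFrame({
        "id": [0, 1, 2],
        "age": [70.2, 65.5, 80.1],
        "sex": ["male", "female", "male"],
        "diag_date": ["2006-01-01"] * 3,
        "diag_year_frac": [2006.0] * 3,
        "time_years": [1.0, 2.0, 3.0],
        "event": [1, 1, 0],
        "edi": [0.0, 1.0, 2.0],
        "edi_q": [3, 3, 3],
        "region": ["R1"] * 3,
    })
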