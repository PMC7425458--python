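import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from methmort import synthgen

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_ref():
    return synthgen.generate_reference_matrix(n_cpgs=120, seed=11)


@pytest.fixture(scope="session")
def small_cohorts(small_ref):
    cfg = synthgen.SimConfig(
        n_cohorts=2,
        n_subjects_per_cohort=150,
        n_cpgs=120,
        missing_rate=0.05,
        baseline_hazard_scale=0.06,
        seed=11,
    )
    return synthgen.generate_cohorts(cfg, small_ref)


@pytest.fixture(scope="session")
def single_cohort(small_cohorts):
    return small_cohorts[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_cox_data(n=80, seed=0, n_covs=2):
    """Small uncensored-ish survival dataset for fitter cross-checks."""
    r = np.random.default_rng(seed)
    X = r.normal(size=(n, n_covs))
    t = np.round(r.exponential(5, n), 1)  # rounding makes ties
    e = (r.random(n) < 0.7).astype(int)
    return X, t, e


@pytest.fixture()
def cox_data():
    return toy_cox_data()
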