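import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stressborn.cohort import attach_covariates, build_observation_bins, senescent_subset
from stressborn.synthetic import SimConfig, simulate_population

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Model-selection loops legitimately emit boundary/aliasing warnings."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="dropping aliased")
        warnings.filterwarnings("ignore", message="excluding non-converged")
        yield


@pytest.fixture(scope="session")
def small_pop() -> pd.DataFrame:
    """A 300-female cohort shared by read-only tests."""
    return simulate_population(SimConfig(n_females=300, seed=7))


@pytest.fixture(scope="session")
def small_bins(small_pop) -> pd.DataFrame:
    return attach_covariates(build_observation_bins(small_pop), small_pop)


@pytest.fixture(scope="session")
def small_senescent(small_bins) -> pd.DataFrame:
    return senescent_subset(small_bins)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_binomial_instance(rng, n_groups=6, per_group=5, sd=0.6, x_slope=0.5):
    """Small random-intercept logistic dataset with known truth."""
    ids = np.repeat(np.arange(n_groups), per_group)
    x = rng.normal(size=len(ids))
    u = rng.normal(0.0, sd, n_groups)
    eta = 0.2 + x_slope * x + u[ids]
    y = (rng.random(len(ids)) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame({"y": y, "x": x, "id": ids})
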