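import numpy as np
import pandas as pd
import pytest

from spatreg import CovarianceParams, SpatialDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def theta():
    return CovarianceParams(nugget=1.0, partial_sill=3.0, range_=0.4)


def make_gp_dataset(n=80, theta=None, beta=(1.0, 2.0, -1.0), seed=0):
    """Small well-specified spatial-regression dataset on the unit square."""
    from spatreg.simulate import simulate_gp_error

    theta = theta or CovarianceParams(1.0, 3.0, 0.4)
    rng = np.random.default_rng(seed)
    coords = rng.uniform(size=(n, 2))
    X = np.column_stack([np.ones(n)] + [rng.uniform(size=n)
                                        for _ in range(len(beta) - 1)])
    y = X @ np.asarray(beta) + simulate_gp_error(coords, theta,
                                                 seed=rng.integers(2 ** 31))
    return coords, X, y


@pytest.fixture
def gp_data():
    return make_gp_dataset()


@pytest.fixture
def toy_sites():
    """Small SpatialDataset with two covariates and two regions."""
    rng = np.random.default_rng(7)
    n = 60
    coords = rng.uniform(size=(n, 2))
    covs = pd.DataFrame({"elev": rng.uniform(0, 10, n),
                         "slope": rng.uniform(size=n)})
    y = 2.0 + 0.5 * covs["elev"].to_numpy() + rng.normal(scale=0.5, size=n)
    region = np.where(coords[:, 0] > 0.5, "east", "west")
    return SpatialDataset(np.arange(n), coords, y, covs, region)
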