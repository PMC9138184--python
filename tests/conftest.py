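import numpy as np
import pytest

import cgcnimp as cg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example_matrix():
    """The worked example: 3 x 5 matrix with '/' (missing) entries as NaN."""
    return np.array([
        [5, np.nan, np.nan, np.nan, 18],
        [12, 32, 9, np.nan, 76],
        [2, np.nan, 24, np.nan, 47],
    ], dtype=float)


@pytest.fixture
def small_dataset(rng):
    """A 30 x 4 partially observed dataset with irregular timestamps."""
    values = rng.normal(size=(30, 4))
    values[rng.random(values.shape) < 0.25] = np.nan
    values[0, :] = 1.0  # keep every attribute observed at least once
    ts = np.cumsum(rng.uniform(0.5, 2.0, size=30))
    return cg.TimeSeriesDataset.from_values(values, timestamps=ts)


@pytest.fixture(scope="session")
def var_sim():
    """Small stationary VAR simulation shared across tests."""
    return cg.simulate_var(d=4, n=400, parents_per_node=2, coef_scale=0.5,
                           noise_sd=0.3, seed=7)


@pytest.fixture(scope="session")
def tiny_benchmark():
    """A small normalized benchmark for fast end-to-end tests."""
    return cg.make_benchmark(cg.SimConfig(d=4, n=300), p_test=0.2, seed=3)
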