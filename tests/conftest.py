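import numpy as np
import pandas as pd
import pytest

from domus.world import WorldConfig, fixture_world, generate_world


@pytest.fixture(scope="session")
def small_world():
    """The 120-society fixture world shared across tests."""
    return fixture_world()


@pytest.fixture(scope="session")
def strong_world():
    """A mid-sized strong-signal world for model-level tests."""
    cfg = WorldConfig(n_societies=300, n_families=20, n_years=10,
                      missing_rate=0.0)
    return generate_world(cfg, seed=42)


@pytest.fixture()
def society_csv(tmp_path):
    """A tiny well-formed 3-row society table on disk."""
    df = pd.DataFrame({
        "society_id": ["A1", "B2", "C3"],
        "lon": [10.5, -75.25, 140.0],
        "lat": [45.0, -12.5, 35.75],
        "language_family": ["famX", "famY", "famX"],
        "ea079": [2, 5, 1], "ea080": [2, 3, 1], "ea081": [8, 5, 1],
        "ea082": [7, 6, 2], "ea009": [4, 1, 2], "ea030": [2, 7, 5],
        "ea033": [5, 1, 3],
        "elevation_m": [120.0, 2400.5, 15.0],
        "slope_deg": [1.5, 12.0, 0.25],
    })
    path = tmp_path / "societies.csv"
    df.to_csv(path, index=False)
    return path, df


def binary_logit_data(seed, n=400, n_groups=0, sigma=0.0,
                      slopes=(1.0, -1.0), intercept=0.0):
    """Simulate grouped binary data from a logistic model (test helper)."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 1.0, (n, len(slopes)))
    eta = intercept + X @ np.asarray(slopes, float)
    groups = None
    if n_groups:
        groups = rng.integers(0, n_groups, n)
        u = rng.normal(0.0, sigma, n_groups)
        eta = eta + u[groups]
    y = np.where(rng.random(n) < 1.0 / (1.0 + np.exp(-eta)), "yes", "no")
    return X, y, groups
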