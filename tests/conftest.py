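"""Shared fixtures: small regression systems and synthetic datasets."""

import numpy as np
import pytest

from gwtls import DesignSystem, SimulationConfig, generate


def make_system(m=12, k=2, seed=0, qa_scale=0.0, qy=None, coord_extent=1000.0):
    """A random well-posed system: y from a true line plus modest noise."""
    rng = np.random.default_rng(seed)
    X = rng.normal(0.0, 2.0, (m, k))
    coords = rng.uniform(0.0, coord_extent, (m, 2))
    x_true = rng.normal(0.0, 1.5, k)
    intercept = rng.normal(0.0, 2.0)
    y = X @ x_true + intercept + rng.normal(0.0, 0.3, m)
    qa = np.full((m, k), qa_scale, dtype=float)
    return DesignSystem.from_features(
        X, y, coords, feature_variances=qa, qy=qy,
        feature_names=[f"f{j}" for j in range(k)],
    )


@pytest.fixture
def small_system():
    return make_system(m=12, k=2, seed=3)


@pytest.fixture
def eiv_system():
    return make_system(m=15, k=2, seed=5, qa_scale=0.05)


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the default synthetic monitoring campaign."""
    return generate(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def station_frame(default_dataset):
    return default_dataset.frame
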