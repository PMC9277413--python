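"""Shared fixtures: a small synthetic plot and a fast tuning protocol.

The small plot (100 x 120 m) keeps unit tests quick; acceptance tests build
the full-size default plot themselves.
"""

import numpy as np
import pytest

from scalewoods import (
    AllometryTable,
    SyntheticConfig,
    TuningProtocol,
    fit_kriging_surface,
    generate_forest,
)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(plot_x=100.0, plot_y=120.0, seed=42)


@pytest.fixture(scope="session")
def small_forest(small_config):
    stems, grid = generate_forest(small_config)
    return stems, grid


@pytest.fixture(scope="session")
def small_surface(small_forest):
    _, grid = small_forest
    return fit_kriging_surface(grid)


@pytest.fixture(scope="session")
def allometry():
    return AllometryTable.default()


@pytest.fixture()
def fast_protocol():
    """Reduced tree counts for unit tests of protocol plumbing."""
    return TuningProtocol(ntree_max=1500, boruta_n_estimators=30,
                          boruta_max_iter=30, mtry_ntree_try=50,
                          importance_repeats=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
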