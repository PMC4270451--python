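import warnings

import numpy as np
import pytest

from hetmeta import (
    HierarchicalConfig,
    McmcConfig,
    default_config,
    fit_hierarchical,
    generate_dataset,
)


@pytest.fixture
def toy_effects():
    """Three-study toy with known Q = 6.0, tau2_DL = 0.08, I2 = 66.7%."""
    return np.array([0.0, 0.0, 0.6]), np.full(3, 0.04)


@pytest.fixture(scope="session")
def small_dataset():
    """A small default-condition synthetic collection with truth."""
    return generate_dataset(default_config(seed=42, n_meta_analyses=80))


@pytest.fixture(scope="session")
def fitted_draws(small_dataset):
    """Hierarchical fit reused across read-only tests."""
    cfg = HierarchicalConfig(
        mcmc=McmcConfig(seed=9, chains=2, burn_in=300, iterations=700)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_hierarchical(small_dataset.collection, cfg)
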