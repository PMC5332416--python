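"""Shared fixtures: small designs, populations, and one reusable fit.

MCMC fits are expensive, so tests that only need *a* fitted posterior share
a single session-scoped fit of a small simulated trial.
"""

import numpy as np
import pytest

import corebreak as cb

# make hypothesis deterministic across the suite
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_design():
    return cb.DesignConfig()


@pytest.fixture(scope="session")
def small_design():
    return cb.DesignConfig(n_genotypes=4, n_blocks=2, n_cores=2, n_depths=8)


@pytest.fixture(scope="session")
def small_pop():
    """Truth matching the small design's two blocks."""
    return cb.DEFAULT_TRUTH.replace(kappa=(0.0, 0.2))


@pytest.fixture(scope="session")
def small_dataset(small_pop, small_design):
    return cb.simulate_dataset(small_pop, small_design, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One short model1 fit shared across read-only posterior tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cb.fit(
            small_dataset, "model1",
            mcmc=cb.McmcConfig(n_chains=2, n_warmup=250, n_draws=250, seed=5),
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
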