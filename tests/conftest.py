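import numpy as np
import pytest

import isosplice as iso


@pytest.fixture(scope="session")
def small_sim():
    """Small DTU simulation shared across tests (200 genes, 5 vs 5)."""
    cfg = iso.SimConfig.desk_scale(seed=11, n_genes=200, resamples=30)
    return iso.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_fit_lm(small_sim):
    model = iso.DTUModel(
        small_sim.bundle, small_sim.catalog, small_sim.design, groups=small_sim.groups
    )
    return model.fit(backend="lm")


@pytest.fixture(scope="session")
def small_fit_nb(small_sim):
    model = iso.DTUModel(
        small_sim.bundle, small_sim.catalog, small_sim.design, groups=small_sim.groups
    )
    return model.fit(backend="nbglm")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
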