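import numpy as np
import pytest
from hypothesis import settings

import mirpls as m

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated campaign (25 standards x 3 replicates, seed 42)."""
    sset, design = m.simulate_dataset(m.SimConfig())
    return sset, design


@pytest.fixture(scope="session")
def averaged_sim(default_sim):
    sset, design = default_sim
    return m.average_replicates(sset), design


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_set(rng):
    """Three random spectra on a 21-point grid."""
    grid = m.WavenumberGrid.from_range(1000, 1020, 1.0)
    return m.SpectrumSet(
        grid=grid,
        absorbance=rng.uniform(0.0, 1.0, size=(3, 21)),
        sample_ids=["a", "b", "c"],
    )
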