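import numpy as np
import pytest

from nirscal.spectra_io import SpectraSet
from nirscal.synthetic import SimConfig, make_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_grid():
    """A 60-point grid for desk-scale tests (same 2 nm step as the default)."""
    return np.arange(1100.0, 1220.0, 2.0)


@pytest.fixture
def toy_spectra(rng, toy_grid):
    X = 0.4 + 0.1 * rng.random((8, toy_grid.size))
    ids = [f"s{i}" for i in range(8)]
    return SpectraSet(toy_grid, X, ids)


def small_sim_config(n_samples=40, seed_grid=True):
    """Reduced-size simulation (short grid) for fast pipeline tests."""
    cfg = SimConfig(n_samples=n_samples)
    cfg.wavelengths = np.arange(1100.0, 2400.0, 4.0)
    return cfg


@pytest.fixture(scope="session")
def small_dataset():
    """One 40-sample dataset on a 325-point grid, shared across tests."""
    cfg = small_sim_config()
    return cfg, *make_dataset(cfg, seed=7)
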