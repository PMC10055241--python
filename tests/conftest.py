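import numpy as np
import pytest

from irfgnet.catalog import load_catalog
from irfgnet.spectra import DEFAULT_GRID, ProcessedSpectrum
from irfgnet.synth import (
    LabeledSpectrum,
    SyntheticConfig,
    dataset_arrays,
    generate_dataset,
    synthetic_catalog,
)


@pytest.fixture(scope="session")
def extended():
    return load_catalog("extended37")


@pytest.fixture(scope="session")
def original():
    return load_catalog("original22")


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 labeled spectra over 4 abstract groups; session-wide, seeded."""
    cat = synthetic_catalog(4)
    cfg = SyntheticConfig(n_samples=60, catalog=cat, seed=11)
    return generate_dataset(cfg), cat


def make_spectrum(values, grid=DEFAULT_GRID):
    return ProcessedSpectrum(np.asarray(values, dtype=float), grid=grid)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
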