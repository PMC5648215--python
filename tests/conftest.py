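import numpy as np
import pandas as pd
import pytest

from ftirchem.spectra import SpectrumSet
from ftirchem.synthetic import SyntheticDesign, BandSpec, default_design


def make_set(intensities, wavenumbers=None, mode="absorbance", **meta_cols):
    """Build a SpectrumSet from a plain matrix with auto metadata."""
    intensities = np.atleast_2d(np.asarray(intensities, float))
    n, p = intensities.shape
    if wavenumbers is None:
        wavenumbers = 4000.0 - 4.0 * np.arange(p)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    for k, v in meta_cols.items():
        meta[k] = v
    return SpectrumSet(wavenumbers, intensities, mode, meta)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_design():
    """Fast variant of the default design: 3 plants/group, 3 replicates."""
    d = default_design()
    d.n_plants_per_group = 3
    d.n_replicates = 3
    return d


@pytest.fixture(scope="session")
def default_set():
    """One full-size simulated study, shared across tests."""
    from ftirchem.synthetic import generate_spectra
    return generate_spectra(default_design(), seed=7)
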