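import numpy as np
import pytest

from tanspec.axes import make_wavelength_axis
from tanspec.synthetic import (
    DEFAULT_ORIGIN_PROFILES,
    BaselineSpec,
    make_dataset,
    simulate_concentrations,
    simulate_reflectance,
)


@pytest.fixture(scope="session")
def mini_axis():
    """A small two-segment axis (20 VNIR + 40 SWIR channels) for fast tests."""
    return make_wavelength_axis(410.0, 30.0, 980.0, 1000.0, 38.0, 40)


@pytest.fixture(scope="session")
def mini_dataset(mini_axis):
    """5 origins x 16 samples on the mini axis, default noise levels."""
    return make_dataset(seed=11, n_per_origin=16, axis=mini_axis)


@pytest.fixture(scope="session")
def noiseless_dataset(mini_axis):
    """Noise-free, scatter-free spectra without origin colour bands.

    In this limit -log(reflectance) is exactly linear in the three analyte
    concentrations, which several oracle tests rely on.
    """
    samples = simulate_concentrations(DEFAULT_ORIGIN_PROFILES, n_per_origin=12, seed=5)
    baseline = BaselineSpec(offset_sd=0.0).without_origin_bands()
    return simulate_reflectance(
        samples, axis=mini_axis, scatter_sd=0.0, baseline=baseline, noise_sd=0.0, seed=5
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
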