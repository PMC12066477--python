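import numpy as np
import pytest

from fvmap.curve_processing import CantileverSpec
from fvmap.synthetic_data import AcquisitionSpec, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def cantilever():
    return CantileverSpec()


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionSpec(noise_sd_nN=0.0)


@pytest.fixture(scope="session")
def two_value_phantom():
    """16x16 phantom with exactly two modulus values (no within-phase jitter)."""
    spec = PhantomSpec(
        grid_n=16,
        glial_modulus_pa=15_000.0,
        axon_modulus_pa=5_000.0,
        axon_area_fraction=0.3,
        modulus_cv=0.0,
        seed=3,
    )
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
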