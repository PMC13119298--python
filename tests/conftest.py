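import numpy as np
import pytest

from polodf.gaunt import gaunt_tensor
from polodf.phantoms import make_shell
from polodf.psf import OpticalConfig, preset_scheme, system_psf
from polodf.simulate import forward_project
from polodf.sphere import SphereGrid


@pytest.fixture(scope="session")
def G():
    return gaunt_tensor()


@pytest.fixture(scope="session")
def oracle_grid():
    """Quadrature grid exact for all band-limited integrands used in tests."""
    return SphereGrid.for_band(12)


@pytest.fixture(scope="session")
def fib_grid():
    return SphereGrid.fibonacci(2562)


@pytest.fixture(scope="session")
def config():
    return OpticalConfig()


@pytest.fixture(scope="session")
def small_setup(config):
    """16^3 shell phantom imaged by a single-view polarized SPIM (circular
    convolution so noise-free data are exactly self-consistent)."""
    shape = (16, 16, 16)
    shell = make_shell(shape, radius=5.5, sigma=1.0)
    scheme = preset_scheme("scheme6").for_view("A")
    resp = system_psf(config, scheme, shape, modality="spim", pad=0)
    meas = forward_project(shell, resp)
    return shell, resp, meas


@pytest.fixture(autouse=True)
def _silence_nyquist_warning():
    """The 130 nm default voxel size intentionally sits above the strict
    Nyquist threshold for NA 1.1; silence that advisory in tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Nyquist.*")
        yield


def rng(seed=0):
    return np.random.default_rng(seed)
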