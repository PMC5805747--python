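import numpy as np
import pytest

from darkfield_thorax.interferometer import (
    AcquisitionSettings,
    ScannerGeometry,
    simulate_reference,
    simulate_scan,
)
from darkfield_thorax.phantom import PhantomConfig, generate_phantom
from darkfield_thorax.retrieval import retrieve


@pytest.fixture(scope="session")
def smoke_config():
    """Smallest valid phantom configuration (4x coarser pixels)."""
    return PhantomConfig.from_calibration(scale="smoke", rng_seed=3)


@pytest.fixture(scope="session")
def smoke_phantom(smoke_config):
    return generate_phantom(smoke_config)


@pytest.fixture(scope="session")
def smoke_geometry():
    return ScannerGeometry.from_calibration(scale="smoke")


@pytest.fixture(scope="session")
def noiseless_settings():
    return AcquisitionSettings.from_calibration(photons_per_step=None)


@pytest.fixture(scope="session")
def noiseless_pair(smoke_phantom, smoke_geometry, noiseless_settings):
    """Noiseless retrieved transmission/dark-field pair of the smoke phantom."""
    reference = simulate_reference(smoke_geometry, noiseless_settings)
    sample = simulate_scan(smoke_phantom, smoke_geometry, noiseless_settings)
    return retrieve(sample, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
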