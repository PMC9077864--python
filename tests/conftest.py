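import numpy as np
import pytest

from clodscan import GroundTruthResponse, LensGeometry, MaterialSpec, ScanConfig


@pytest.fixture
def truth():
    return GroundTruthResponse(lin_coeff=0.3, pow_coeff=0.1, exponent=1.8)


@pytest.fixture
def geometry():
    return LensGeometry()


@pytest.fixture
def quiet_material():
    """A noiseless, ring-free material for degenerate-generator checks."""
    return MaterialSpec(name="ideal", refractive_index=1.51, pixel_noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scan_config():
    return ScanConfig(mode="transmission", seed=7)
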