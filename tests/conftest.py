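import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def minimal_image():
    """Smallest conformant single-voxel image."""
    from niftimrs import make_minimal

    fid = np.exp(-np.arange(512) * 0.01).astype(np.complex64)
    return make_minimal(fid, dwell_s=5e-4, f0_mhz=123.2, nucleus="1H")
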