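import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaborholo.optics import ComplexField, GridSpec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid64():
    return GridSpec(64, 64, 2e-6)


@pytest.fixture
def grid128():
    return GridSpec(128, 128, 2e-6)


def random_bandlimited_field(grid: GridSpec, wavelength: float, rng, sigma_px: float = 2.0):
    """Seeded random complex field smoothed to suppress near-Nyquist content."""
    from gaborholo.reconstruct import gaussian_lowpass

    raw = rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
    return ComplexField(gaussian_lowpass(raw, sigma_px), grid, wavelength)
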