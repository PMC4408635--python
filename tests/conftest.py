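import numpy as np
import pytest

from endoshape import CameraModel, SphereSurface, CosineSurface, render


@pytest.fixture(scope="session")
def camera_96():
    """Small camera for fast unit tests: 9 x 9 mm sensor, 96 x 96 pixels."""
    return CameraModel(10.0, (9.0, 9.0), (96, 96))


@pytest.fixture(scope="session")
def train_sphere():
    return SphereSurface(center=(0.0, 0.0, 15.0), radius=5.0)


@pytest.fixture(scope="session")
def test_sphere():
    return SphereSurface(center=(0.0, 0.0, 15.0), radius=3.0)


@pytest.fixture(scope="session")
def cosine_surface():
    return CosineSurface(base_depth=12.0, wavelength=4.0, amplitude=1.0)


@pytest.fixture(scope="session")
def sphere_bundle_96(camera_96, train_sphere):
    return render(train_sphere, camera_96, C=100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
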