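import numpy as np
import pytest

from cryostack import PhantomSpec, RasterVolume, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20231001)


@pytest.fixture
def random_volume(rng):
    """Small random-color volume: 6 layers of 24x20 px, pitch 8, step 10."""
    stack = rng.integers(0, 256, size=(6, 20, 24, 3), dtype=np.uint8)
    return RasterVolume.from_array(stack, step_um=10.0, pitch_um=8.0)


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noiseless sphere phantom, R=100 um, pitch 8, step 10, centered on grid."""
    spec = PhantomSpec(shape="sphere", shape_params={"radius_um": 100.0},
                       canvas=(64, 64), seed=11)
    return make_phantom(spec)


def equivalent_radius_um(mask: np.ndarray, pitch_um: float) -> float:
    """Radius of the disc with the same pixel area as the mask."""
    return float(np.sqrt(mask.sum() / np.pi) * pitch_um)
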