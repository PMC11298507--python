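import numpy as np
import pytest

from interpsplit import io, phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_spec():
    """Desk-scale phantom whose terminal branches are sub-resolution for the
    threshold-opening backend at ir=1 (radius 0.86 voxels, diameter ~1.7,
    vs a disk(2) structuring element)."""
    return phantom.PhantomSpec(
        grid_shape=(64, 96, 96),
        generations=4,
        root_radius=4.0,
        radius_decay=0.6,
        length_root=20.0,
        length_decay=0.8,
        branch_half_angle=35.0,
        angle_jitter=5.0,
        wall_thickness=1.5,
        noise_sigma=3.0,
        psf_sigma=0.4,
        min_radius=0.5,
        seed=1,
    )


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return phantom.generate_phantom(desk_spec)


@pytest.fixture(scope="session")
def normalized_phantom(desk_phantom):
    """The desk phantom's image, window/level normalized to [0, 255]."""
    return io.window_level_normalize(io.Volume(desk_phantom.image)).data


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, blur-free small phantom for exact-value checks."""
    return phantom.PhantomSpec(
        grid_shape=(48, 64, 64),
        generations=3,
        root_radius=3.0,
        radius_decay=0.6,
        length_root=16.0,
        length_decay=0.8,
        noise_sigma=0.0,
        psf_sigma=0.0,
        seed=7,
    )
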