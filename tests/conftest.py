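import numpy as np
import pytest

from adcroi import ADCVolume, LesionMask3D, PhantomConfig, generate_phantom


def random_volume_and_mask(rng, shape=(3, 16, 16), fill=0.5):
    """Seeded random ADC volume + mask with at least one voxel set."""
    vals = rng.uniform(400.0, 1600.0, size=shape)
    mask = rng.random(shape) < fill
    if not mask.any():
        mask[tuple(d // 2 for d in shape)] = True
    return ADCVolume(values=vals), LesionMask3D(voxels=mask)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_volume(rng):
    return random_volume_and_mask(rng)


@pytest.fixture(scope="session")
def sharp_phantom():
    """Noiseless phantom with crisp level sets (no blur, no texture)."""
    cfg = PhantomConfig(
        noise_sd=0.0,
        background_sd=0.0,
        lesion_texture_sd=0.0,
        boundary_smooth_sigma=0.0,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomConfig(seed=7), compute_truth=False)
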