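import numpy as np
import pytest

from spheroct import OCTVolume, PhantomSpec


def make_ball_volume(radius_vox: int, pitch: float = 1.0, value: float = 1.0,
                     pad: int = 4) -> tuple[OCTVolume, np.ndarray]:
    """Digital ball (centered, radius in voxels) in a zero background."""
    n = 2 * radius_vox + 2 * pad + 1
    c = radius_vox + pad
    zz, xx, yy = np.mgrid[:n, :n, :n]
    mask = (zz - c) ** 2 + (xx - c) ** 2 + (yy - c) ** 2 <= (radius_vox + 0.5) ** 2
    vol = OCTVolume(mask.astype(float) * value, (pitch, pitch, pitch))
    return vol, mask


def small_spec(**overrides) -> PhantomSpec:
    """A fast, clean phantom spec suitable for unit tests."""
    kwargs = dict(
        grid_shape=(72, 72, 72),
        voxel_pitch_um=(2.0, 2.0, 2.0),
        n_spheroids=1,
        radius_range_um=(40, 55),
        speckle=False,
        attenuation_coeff=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
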