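import numpy as np
import pytest

from ldcnet.image_io import CTVolume
from ldcnet.network import NetworkSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_volume(rng):
    """A 4x4x4 integer HU volume with non-trivial metadata."""
    voxels = rng.integers(-1000, 400, size=(4, 4, 4), dtype=np.int16)
    return CTVolume(
        voxels=voxels,
        origin_mm=np.array([-100.0, -100.0, -50.0]),
        spacing_mm=np.array([0.7, 0.7, 2.5]),
        direction=np.eye(3),
    )


@pytest.fixture
def tiny_spec():
    """A small-but-real LdcNet variant for fast training tests."""
    return NetworkSpec(
        input_side=20,
        n_blocks=2,
        filters_per_block=[4, 8],
        kernel_per_block=[5, 3],
        fc_width=16,
        dropout_rate=0.5,
    )
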