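import numpy as np
import pytest

from vesselcam import CameraIntrinsics, RigGeometry


@pytest.fixture
def small_rig():
    """Test-scale rig: 480 x 270 (aspect-preserving scale of full HD), 0.30 m."""
    return RigGeometry(image_size=(480, 270), object_distance=0.30)


@pytest.fixture
def ideal_intrinsics(small_rig):
    return small_rig.default_intrinsics()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
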