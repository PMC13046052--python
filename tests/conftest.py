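import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tomosynth.geometry import AcquisitionGeometry
from tomosynth.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-like geometry with a small detector for projector tests."""
    return AcquisitionGeometry(
        sdd_mm=1800.0, sweep_deg=(-15.0, 15.0), n_views=9,
        detector_shape=(33, 33), detector_pitch_mm=2.0,
        patient_offset_mm=150.0, strip_width_px=5)


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec(grid_shape=(48, 48, 48), voxel_size_mm=3.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
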