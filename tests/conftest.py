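import numpy as np
import pytest

from larvamotor.kinematics import PointTrack


def track_from_points(rows, frame_rate=300.0):
    """Build a PointTrack from explicit (Hx,Hy,Mx,My,Tx,Ty) rows."""
    return PointTrack(frame_rate=frame_rate, coords=np.asarray(rows, dtype=float))


@pytest.fixture
def rest_track():
    """Two frames of a perfectly straight larva (theta = 180 deg)."""
    return track_from_points([[0, 1, 0, 0, 0, -1]] * 2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
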