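import numpy as np
import pytest

from podomot.tracking import Track, TrackPoint


def make_track(coords, times=None, cell_id="c1", condition="vehicle", frames=None):
    """Build a Track from a list of (x, y) coordinates."""
    coords = np.asarray(coords, dtype=float)
    if times is None:
        times = np.arange(len(coords), dtype=float)
    if frames is None:
        frames = np.arange(len(coords))
    points = [
        TrackPoint(frame=int(f), time=float(t), x=float(x), y=float(y))
        for f, t, (x, y) in zip(frames, times, coords)
    ]
    return Track(cell_id=cell_id, condition=condition, points=points)


@pytest.fixture
def make_track_fixture():
    return make_track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
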