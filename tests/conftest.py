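import numpy as np
import pytest

from axotraffic.track_motion import Track, TrackMotionConfig


@pytest.fixture
def cfg() -> TrackMotionConfig:
    return TrackMotionConfig()


def make_track(x, track_id="t0", axon_id="a0") -> Track:
    x = np.asarray(x, dtype=float)
    return Track(track_id=track_id, frames=np.arange(len(x)), x_px=x, axon_id=axon_id)


@pytest.fixture
def make_track_fn():
    return make_track


def random_integer_track(rng: np.random.Generator, n: int) -> Track:
    """Random integer-pixel track with mixed dwell/step behavior."""
    steps = rng.integers(-2, 3, size=n - 1)
    # sprinkle dwelling stretches so pauses appear
    mask = rng.random(n - 1) < 0.4
    steps[mask] = 0
    x = np.concatenate(([0], np.cumsum(steps))).astype(float)
    return make_track(x)
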