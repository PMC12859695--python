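import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "wormassay",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("wormassay")


def make_track(centroid, head=None, dt=0.1, valid=None, animal_id="w0",
               **kwargs):
    """Build a Track from explicit positions (head defaults to centroid)."""
    from wormassay import Track

    centroid = np.asarray(centroid, dtype=float)
    n = len(centroid)
    return Track(
        animal_id=animal_id,
        times=np.arange(n) * dt,
        centroid=centroid,
        head=np.asarray(head, dtype=float) if head is not None else centroid.copy(),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        nominal_dt=dt,
        **kwargs,
    )


@pytest.fixture
def straight_track():
    """Eastward motion at 0.5 mm/s, 0.1 s frames, head == centroid."""
    x = np.arange(20) * 0.05
    return make_track(np.column_stack([x, np.zeros_like(x)]))
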