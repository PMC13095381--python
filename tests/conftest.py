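import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles.py importable

from reachlearn.config import TrackingBounds  # noqa: E402
from reachlearn.tracking_io import FilteredTrack  # noqa: E402


WIDE_BOUNDS = TrackingBounds(-1e6, 1e6, -1e6, 1e6)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def make_filtered(frames, xy, bounds=WIDE_BOUNDS, point="right_paw"):
    frames = np.asarray(frames, dtype=np.int64)
    return FilteredTrack(
        point=point,
        frames=frames,
        xy=np.asarray(xy, dtype=float),
        likelihood=np.full(len(frames), 0.99),
        p_cutoff=0.85,
        bounds=bounds,
    )


def random_filtered_track(rng, max_len=200, pellet=(50.0, 0.0)):
    """A random filtered paw track mixing drifts toward/away from the pellet,
    dwell periods and occasional frame gaps."""
    n = int(rng.integers(0, max_len + 1))
    gaps = rng.choice([1, 1, 1, 1, 2, 3, 9], size=max(n, 1))
    frames = np.cumsum(gaps)[:n]
    pos = np.array([rng.uniform(-80, 80), rng.uniform(-80, 80)])
    pts = []
    mode = rng.choice(["toward", "away", "dwell"])
    for _ in range(n):
        if rng.random() < 0.08:
            mode = rng.choice(["toward", "away", "dwell"])
        if mode == "dwell":
            step = rng.normal(0, 0.8, 2)
        else:
            to_pellet = np.asarray(pellet) - pos
            d = np.linalg.norm(to_pellet)
            u = to_pellet / d if d > 1e-9 else np.array([1.0, 0.0])
            sign = 1.0 if mode == "toward" else -1.0
            step = sign * u * rng.uniform(1, 6) + rng.normal(0, 0.8, 2)
        pos = pos + step
        pts.append(pos.copy())
    xy = np.asarray(pts, dtype=float).reshape(-1, 2)
    return make_filtered(frames, xy)
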