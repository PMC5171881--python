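import numpy as np
import pandas as pd
import pytest

from synaptrack import LocalizationTable, Trajectory


@pytest.fixture
def simple_track():
    """Three-point track with hand-computable MSD."""
    return Trajectory("t0", [0, 1, 2], [0.0, 0.1, 0.3], [0.0, 0.0, 0.1],
                      dt=0.03)


@pytest.fixture
def stationary_track():
    return Trajectory("still", np.arange(10), np.full(10, 1.5),
                      np.full(10, -2.0), dt=1 / 33)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tracks(rng, n=20, min_len=2, max_len=30, dt=1 / 33, d=0.05):
    """Brownian test tracks with random lengths."""
    tracks = []
    for i in range(n):
        npts = int(rng.integers(min_len, max_len + 1))
        steps = rng.normal(0.0, np.sqrt(2 * d * dt), size=(npts - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        tracks.append(Trajectory(f"r{i}", np.arange(npts), pos[:, 0],
                                 pos[:, 1], dt=dt))
    return tracks


@pytest.fixture
def five_record_blinks():
    """Records 1-2-3 form a transitive chain (1-frame gaps, 0.5 px apart);
    records 4 and 5 are isolated."""
    df = pd.DataFrame({
        "frame": [0, 1, 2, 0, 5],
        "x": [100.0, 140.0, 120.0, 600.0, 95.0],
        "y": [100.0, 90.0, 115.0, 600.0, 400.0],
        "intensity": [1.0, 2.0, 3.0, 4.0, 5.0],
    })
    return LocalizationTable(df=df, fov=(0.0, 1000.0, 0.0, 1000.0),
                             pixel_size_camera=100.0)
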