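import numpy as np
import pytest

from wormtrack.simulate import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """Small, fast single-worm recording with default optics."""
    return SimulationConfig(arena_size=(300, 300), n_worms=1, duration=30.0,
                            steer_margin=1000.0, seed=42)


@pytest.fixture
def behavior_config() -> SimulationConfig:
    """Behavior-only configuration for trajectory-level tests."""
    return SimulationConfig(n_worms=5, duration=120.0, seed=7)


def make_track(centroids_um, frames=None, n_holes=None, um_per_px=15.0,
               midlines_um=None, track_id=0):
    """Build a Track directly from arrays (test helper)."""
    from wormtrack.track import Track

    centroids_um = np.asarray(centroids_um, dtype=float)
    n = len(centroids_um)
    if frames is None:
        frames = np.arange(n)
    if n_holes is None:
        n_holes = np.zeros(n, dtype=int)
    return Track(track_id=track_id, frames=np.asarray(frames),
                 centroids_um=centroids_um, areas_px=np.full(n, 100.0),
                 n_holes=np.asarray(n_holes), midlines_um=midlines_um,
                 um_per_px=um_per_px)
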