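import numpy as np
import pytest

from chemotax import (AcquisitionParams, GroundTruthTrack, MotilityParams,
                      make_default_geometry)

#: Small device used throughout the unit tests: 3 channels per side,
#: 1 um/px so pixel and micron coordinates coincide.
SMALL_GEOMETRY_CONFIG = {
    "channel_length_um": 120.0,
    "chamber_width_um": 80.0,
    "field_height_um": 200.0,
    "n_channels": 3,
    "pixel_size_um": 1.0,
}


@pytest.fixture(scope="session")
def small_geometry():
    return make_default_geometry(SMALL_GEOMETRY_CONFIG)


@pytest.fixture(scope="session")
def full_geometry():
    """The default ten-channel device."""
    return make_default_geometry()


@pytest.fixture
def short_acquisition():
    """16 frames at the standard 4-min interval, noise-free rendering."""
    return AcquisitionParams(duration=60.0, pixel_size=1.0, seed=7,
                             shot_noise=False, gaussian_sd=0.0)


def make_static_track(track_id, x, y, n_frames, radius=3.0,
                      frame_interval=4.0, region="CENTER"):
    """Ground-truth track of a cell that never moves."""
    return GroundTruthTrack(
        track_id=track_id,
        frames=np.arange(n_frames),
        times=np.arange(n_frames) * frame_interval,
        x=np.full(n_frames, float(x)),
        y=np.full(n_frames, float(y)),
        radius=np.full(n_frames, float(radius)),
        regions=[region] * n_frames,
    )


def make_path_track(track_id, xs, ys, radius=3.0, frame_interval=4.0,
                    region="CENTER"):
    """Ground-truth track following explicit coordinates."""
    xs = np.asarray(xs, float)
    n = len(xs)
    return GroundTruthTrack(
        track_id=track_id,
        frames=np.arange(n),
        times=np.arange(n) * frame_interval,
        x=xs, y=np.asarray(ys, float),
        radius=np.full(n, float(radius)),
        regions=[region] * n,
    )


@pytest.fixture
def ballistic_motility():
    """Noise-free, highly persistent, unbiased motility."""
    return MotilityParams(n_cells=10, speed_mean=4.0, speed_sd=0.0,
                          persistence=0.9, bias_left=0.0, bias_right=0.0,
                          turn_kappa=np.inf, channel_entry_prob=1.0)
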