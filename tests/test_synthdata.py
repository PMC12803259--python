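import numpy as np
import pandas as pd
import pytest

from chemotax import (AcquisitionParams, BACKGROUND, MotilityParams,
                      ParameterError, count_by_region, make_default_geometry,
                      percent_migrated, read_fixture, render_frames,
                      simulate_tracks, straightness, tracks_to_dataframe,
                      write_fixture)
from conftest import SMALL_GEOMETRY_CONFIG, make_static_track


# ---------------------------------------------------------------- parameters

def test_invalid_parameters_are_rejected():
    with pytest.raises(ParameterError):
        AcquisitionParams(frame_interval=0.0)
    with pytest.raises(ParameterError):
        AcquisitionParams(duration=1.0, frame_interval=4.0)
    with pytest.raises(ParameterError):
        MotilityParams(speed_mean=-1.0)
    with pytest.raises(ParameterError):
        MotilityParams(persistence=1.0)
    with pytest.raises(ParameterError):
        MotilityParams(bias_left=np.inf)


def test_default_acquisition_has_61_frames():
    acq = AcquisitionParams()
    assert acq.n_frames == 61
    assert acq.times[-1] == 240.0


def test_zero_cells_is_a_parameter_error(small_geometry, short_acquisition):
    with pytest.raises(ParameterError):
        simulate_tracks(small_geometry, MotilityParams(n_cells=0),
                        short_acquisition)


# ---------------------------------------------------------------- simulation

def test_unbiased_walk_has_symmetric_x_displacement(small_geometry):
    """With zero bias and zero persistence the mean signed x-displacement
    over many cells is statistically indistinguishable from zero."""
    acq = AcquisitionParams(duration=60.0, pixel_size=1.0, seed=11)
    mot = MotilityParams(n_cells=400, persistence=0.0, bias_left=0.0,
                        bias_right=0.0, channel_entry_prob=0.0)
    tracks = simulate_tracks(small_geometry, mot, acq)
    dx = np.array([tr.x[-1] - tr.x[0] for tr in tracks])
    se = dx.std(ddof=1) / np.sqrt(len(dx))
    assert abs(dx.mean()) < 3 * se


def test_ballistic_limit_gives_straight_constant_speed_paths(
        ballistic_motility):
    """persistence -> 1 with zero angular noise: straight paths whose length
    is speed x elapsed time (for cells that never touch a wall)."""
    geom = make_default_geometry({
        "channel_length_um": 50.0, "chamber_width_um": 3000.0,
        "field_height_um": 3000.0, "n_channels": 1, "pixel_size_um": 1.0})
    acq = AcquisitionParams(duration=40.0, seed=5)
    tracks = simulate_tracks(geom, ballistic_motility, acq)
    speed, dt = ballistic_motility.speed_mean, acq.frame_interval
    checked = 0
    cc = geom.center_chamber
    for tr in tracks:
        margin = speed * acq.duration
        if (cc.x0 + margin < tr.x[0] < cc.x1 - margin
                and cc.y0 + margin < tr.y[0] < cc.y1 - margin):
            df = pd.DataFrame({"frame": tr.frames, "t_min": tr.times,
                               "x_um": tr.x, "y_um": tr.y})
            assert straightness(df) > 0.999
            path = np.hypot(np.diff(tr.x), np.diff(tr.y)).sum()
            assert path == pytest.approx(speed * acq.duration, rel=1e-9)
            checked += 1
    assert checked >= 3  # seed guarantees interior starters exist


def test_channel_migration_is_quasi_one_dimensional(small_geometry):
    """Inside a migration channel cells move along the channel axis only."""
    mot = MotilityParams(n_cells=50, bias_right=2.0, bias_left=0.0,
                        channel_entry_prob=1.0, persistence=0.8)
    acq = AcquisitionParams(duration=120.0, seed=2)
    tracks = simulate_tracks(small_geometry, mot, acq)
    saw_channel_step = False
    for tr in tracks:
        for k in range(1, len(tr)):
            if (tr.regions[k - 1].startswith("CHANNEL")
                    and tr.regions[k].startswith("CHANNEL")):
                assert tr.y[k] == tr.y[k - 1]
                saw_channel_step = True
    assert saw_channel_step


def test_rightward_bias_sends_more_cells_right_than_left(full_geometry):
    """Sign test across independent seeds: with bias_right >> bias_left more
    cells reach the right chamber than the left by the final frame."""
    wins = 0
    for seed in range(5):
        mot = MotilityParams(n_cells=80, bias_right=0.6, bias_left=0.0)
        tracks = simulate_tracks(full_geometry, mot,
                                 AcquisitionParams(seed=seed))
        last = [tr.regions[-1] for tr in tracks]
        right = sum(r in ("CHAMBER_RIGHT", "CHANNEL_RIGHT") for r in last)
        left = sum(r in ("CHAMBER_LEFT", "CHANNEL_LEFT") for r in last)
        wins += right > left
    assert wins == 5


def test_closed_world_and_region_consistency(small_geometry,
                                             short_acquisition):
    """Cells never leave the device, every frame has every cell, and stored
    region labels agree with the geometry."""
    mot = MotilityParams(n_cells=30)
    tracks = simulate_tracks(small_geometry, mot, short_acquisition)
    n_frames = short_acquisition.n_frames
    for tr in tracks:
        assert len(tr) == n_frames
        assert list(tr.frames) == list(range(n_frames))
        for k in range(n_frames):
            region, _ = small_geometry.assign_region(tr.x[k], tr.y[k])
            assert region == tr.regions[k]
            assert region != BACKGROUND
    df = tracks_to_dataframe(tracks)
    assert (df.groupby("frame").size() == mot.n_cells).all()


def test_same_seed_reproduces_tracks_and_prenoise_frames(small_geometry,
                                                         short_acquisition):
    mot = MotilityParams(n_cells=10)
    t1 = simulate_tracks(small_geometry, mot, short_acquisition)
    t2 = simulate_tracks(small_geometry, mot, short_acquisition)
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)
        assert a.regions == b.regions
    f1 = render_frames(t1, small_geometry, short_acquisition)
    f2 = render_frames(t2, small_geometry, short_acquisition)
    np.testing.assert_array_equal(f1.frames, f2.frames)


# ---------------------------------------------------------------- rendering

def test_static_cell_renders_at_its_centroid(small_geometry,
                                             short_acquisition):
    cx, cy = small_geometry.center_chamber.center
    tr = make_static_track(0, cx, cy, short_acquisition.n_frames)
    images = render_frames([tr], small_geometry, short_acquisition)
    for frame in images.frames:
        iy, ix = np.unravel_index(np.argmax(frame), frame.shape)
        assert abs(ix - cx) <= 1 and abs(iy - cy) <= 1


def test_empty_scene_is_background_only(small_geometry, short_acquisition):
    images = render_frames([], small_geometry, short_acquisition)
    np.testing.assert_allclose(images.frames,
                               short_acquisition.background_level)


def test_well_separated_cells_give_two_local_maxima(small_geometry,
                                                    short_acquisition):
    cx, cy = small_geometry.center_chamber.center
    sep = 8 * short_acquisition.psf_sigma  # > 6 sigma apart
    tracks = [make_static_track(0, cx - sep / 2, cy, 1),
              make_static_track(1, cx + sep / 2, cy, 1)]
    acq = AcquisitionParams(duration=4.0, pixel_size=1.0, seed=0,
                            shot_noise=False, gaussian_sd=0.0)
    frame = render_frames(tracks, small_geometry, acq).frames[0]
    interior = frame[1:-1, 1:-1]
    is_max = ((interior > frame[:-2, 1:-1]) & (interior > frame[2:, 1:-1])
              & (interior > frame[1:-1, :-2]) & (interior > frame[1:-1, 2:])
              & (interior > acq.background_level + 1))
    assert is_max.sum() == 2


def test_integrated_blob_intensity_scales_with_cell_area(small_geometry):
    """Total fluorescence above background is proportional to pi r^2."""
    acq = AcquisitionParams(duration=4.0, pixel_size=1.0, seed=0,
                            shot_noise=False, gaussian_sd=0.0)
    cx, cy = small_geometry.center_chamber.center
    sums = []
    for r in (2.0, 4.0):
        tr = make_static_track(0, cx, cy, 1, radius=r)
        frame = render_frames([tr], small_geometry, acq).frames[0]
        sums.append((frame - acq.background_level).sum())
    assert sums[1] / sums[0] == pytest.approx(4.0, rel=0.01)


# ---------------------------------------------------------------- fixtures

def test_fixture_round_trips_losslessly(tmp_path, small_geometry,
                                        short_acquisition):
    mot = MotilityParams(n_cells=5)
    tracks = simulate_tracks(small_geometry, mot, short_acquisition)
    images = render_frames(tracks, small_geometry, short_acquisition)
    manifest = write_fixture(tracks, images, tmp_path,
                             geometry=small_geometry,
                             acquisition=short_acquisition, motility=mot)
    assert manifest["seed"] == short_acquisition.seed
    back = read_fixture(tmp_path)
    np.testing.assert_array_equal(back["images"].frames, images.frames)
    np.testing.assert_array_equal(back["images"].times, images.times)
    assert back["geometry"] == small_geometry
    pd.testing.assert_frame_equal(
        back["tracks"],
        pd.read_csv(tmp_path / "tracks.csv"))


def test_same_seed_gives_byte_identical_ground_truth_csv(
        tmp_path, small_geometry, short_acquisition):
    mot = MotilityParams(n_cells=5)
    blobs = []
    for sub in ("a", "b"):
        tracks = simulate_tracks(small_geometry, mot, short_acquisition)
        write_fixture(tracks, None, tmp_path / sub,
                      acquisition=short_acquisition)
        blobs.append((tmp_path / sub / "tracks.csv").read_bytes())
    assert blobs[0] == blobs[1]


def test_generator_sweep_feeds_percentage_metric(full_geometry):
    """Smoke check: ground-truth tracks flow into the percentage readout."""
    mot = MotilityParams(n_cells=60, bias_right=0.4)
    df = tracks_to_dataframe(
        simulate_tracks(full_geometry, mot, AcquisitionParams(seed=1)))
    series = count_by_region(df)
    assert series.n_total == 60
    pct = percent_migrated(series, "right")
    assert 0.0 <= pct <= 100.0
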