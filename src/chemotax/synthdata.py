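"""Synthetic time-lapse generation for the chemotaxis device.

No public image dataset accompanies this assay, so every downstream stage is
validated against simulated ground truth: cells perform a biased persistent
random walk inside the device geometry (quasi-1-D inside migration channels),
and each stained nucleus is rendered as a Gaussian intensity blob onto a
noisy fluorescence background.

The acquisition defaults mirror the assay protocol: one frame every 4 minutes
for 4 hours (61 frames), 10x magnification. Motility defaults span the
4.5-10 um/min single-cell velocity range typical of murine neutrophils in
these devices, with a chemotactic bias toward the right (LTB4) side.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .geometry import DeviceGeometry, geometry_from_dict, geometry_to_dict

GROUND_TRUTH_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um",
                        "radius_um", "region"]


@dataclass(frozen=True)
class AcquisitionParams:
    """Imaging parameters: frame timing, optics and noise model."""

    frame_interval: float = 4.0     # minutes between frames
    duration: float = 240.0         # total recording, minutes
    pixel_size: float = 0.65        # um per pixel (10x lens)
    psf_sigma: float = 2.0          # point-spread sigma, pixels
    background_level: float = 100.0  # camera background, intensity units
    intensity_per_um2: float = 300.0  # integrated blob intensity per um^2 of cell
    shot_noise: bool = True
    gaussian_sd: float = 3.0        # additive read noise, intensity units
    seed: int = 0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.duration < self.frame_interval:
            raise ParameterError("duration must be >= frame_interval")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration / self.frame_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        """Frame times in minutes."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class MotilityParams:
    """Biased persistent random walk parameters.

    ``persistence`` weights the previous step direction, ``bias_left`` /
    ``bias_right`` are drift strengths toward each chemoattractant side
    (the net drift is their difference along x), and ``turn_kappa`` is the
    von Mises concentration of the per-step angular noise
    (``inf`` = noise-free).
    """

    n_cells: int = 100
    speed_mean: float = 6.5        # um/min
    speed_sd: float = 1.5          # um/min
    persistence: float = 0.6       # in [0, 1)
    bias_left: float = 0.05
    bias_right: float = 0.3
    turn_kappa: float = 4.0
    channel_entry_prob: float = 0.2  # per-frame entry prob at a channel mouth
    cell_radius_mean: float = 3.0  # um (neutrophil nucleus scale)
    cell_radius_sd: float = 0.4    # um

    def __post_init__(self):
        if self.speed_mean <= 0:
            raise ParameterError("speed_mean must be positive")
        if self.speed_sd < 0:
            raise ParameterError("speed_sd must be >= 0")
        if not 0 <= self.persistence < 1:
            raise ParameterError("persistence must be in [0, 1)")
        if not (np.isfinite(self.bias_left) and np.isfinite(self.bias_right)):
            raise ParameterError("bias parameters must be finite")
        if self.bias_left < 0 or self.bias_right < 0:
            raise ParameterError("bias parameters must be >= 0")
        if not 0 <= self.channel_entry_prob <= 1:
            raise ParameterError("channel_entry_prob must be in [0, 1]")
        if self.cell_radius_mean <= 0:
            raise ParameterError("cell_radius_mean must be positive")


@dataclass
class GroundTruthTrack:
    """True trajectory of one simulated cell, one record per frame."""

    track_id: int
    frames: np.ndarray     # strictly increasing frame indices
    times: np.ndarray      # minutes
    x: np.ndarray          # um
    y: np.ndarray          # um
    radius: np.ndarray     # um, one per frame (constant in this model)
    regions: list[str]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class ImageSequence:
    """Time-indexed stack of 2-D intensity frames with physical calibration."""

    frames: np.ndarray     # (T, H, W) float32
    times: np.ndarray      # minutes, strictly increasing, equally spaced
    pixel_size: float      # um per pixel

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ParameterError("frames must be a (T, H, W) stack")
        if len(self.times) != len(self.frames):
            raise ParameterError("len(times) must equal number of frames")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0]):
                raise ParameterError(
                    "times must be strictly increasing and equally spaced")

    def __len__(self) -> int:
        return len(self.frames)


def _reflect_candidates(x, y, dx, dy):
    """Candidate reflected endpoints, in preference order."""
    return ((x + dx, y - dy), (x - dx, y + dy), (x - dx, y - dy))


def simulate_tracks(geometry: DeviceGeometry,
                    motility: MotilityParams,
                    acquisition: AcquisitionParams,
                    rng: np.random.Generator | None = None,
                    ) -> list[GroundTruthTrack]:
    """Simulate biased persistent random walks inside the device.

    Cells start uniformly in the center loading chamber. Per step the mean
    heading is the persistence-weighted previous direction plus a drift of
    magnitude ``bias_right - bias_left`` along +x; the realized heading adds
    von Mises angular noise. The step length is speed x frame interval.
    Inside a migration channel motion is quasi-1-D along the channel axis.
    Walls reflect; no cell ever leaves the device (closed world).

    Deterministic for a fixed ``acquisition.seed`` (or supplied ``rng``).
    """
    if motility.n_cells <= 0:
        raise ParameterError("n_cells must be >= 1")
    n_frames = acquisition.n_frames
    if n_frames < 1:
        raise ParameterError("acquisition yields zero frames")
    if rng is None:
        rng = np.random.default_rng(acquisition.seed)

    dt = acquisition.frame_interval
    times = acquisition.times
    cc = geometry.center_chamber

    n = motility.n_cells
    xs = rng.uniform(cc.x0, cc.x1, size=n)
    ys = rng.uniform(cc.y0, cc.y1, size=n)
    speeds = np.clip(rng.normal(motility.speed_mean, motility.speed_sd, size=n),
                     0.2, None)
    radii = np.clip(
        rng.normal(motility.cell_radius_mean, motility.cell_radius_sd, size=n),
        0.5, None)
    thetas = rng.uniform(-np.pi, np.pi, size=n)

    drift = motility.bias_right - motility.bias_left  # net drift along +x

    tracks = []
    for i in range(n):
        tracks.append(GroundTruthTrack(
            track_id=i,
            frames=np.arange(n_frames),
            times=times.copy(),
            x=np.empty(n_frames), y=np.empty(n_frames),
            radius=np.full(n_frames, radii[i]),
            regions=[""] * n_frames))
        tracks[i].x[0], tracks[i].y[0] = xs[i], ys[i]
        tracks[i].regions[0] = geometry.region_of(xs[i], ys[i])

    for f in range(1, n_frames):
        for i in range(n):
            tr = tracks[i]
            x, y = tr.x[f - 1], tr.y[f - 1]
            region = tr.regions[f - 1]
            step = speeds[i] * dt

            # mean heading: persistence + chemotactic drift
            mx = motility.persistence * np.cos(thetas[i]) + drift
            my = motility.persistence * np.sin(thetas[i])
            norm = np.hypot(mx, my)
            mu = np.arctan2(my, mx) if norm > 1e-12 else rng.uniform(-np.pi, np.pi)
            if np.isinf(motility.turn_kappa):
                theta = mu
            else:
                theta = mu + rng.vonmises(0.0, motility.turn_kappa)

            in_channel = region.startswith("CHANNEL")
            if in_channel:
                # quasi-1-D: full step along the channel axis
                sgn = np.sign(np.cos(theta)) or np.sign(np.cos(thetas[i])) or 1.0
                nx, ny = x + sgn * step, y
                theta = 0.0 if sgn > 0 else np.pi
                if not geometry.in_device(nx, ny):
                    nx = x - sgn * step  # bounce off a blocked end
                    theta = np.pi - theta
                    if not geometry.in_device(nx, ny):
                        nx = x
            else:
                dx, dy = step * np.cos(theta), step * np.sin(theta)
                nx, ny = x + dx, y + dy
                ok = geometry.in_device(nx, ny)
                if ok:
                    new_region = geometry.region_of(nx, ny)
                    if (new_region.startswith("CHANNEL")
                            and rng.uniform() >= motility.channel_entry_prob):
                        ok = False  # balked at the channel mouth
                if not ok:
                    # reflect off the wall; a channel mouth can only be
                    # entered by a direct move that passed the entry draw,
                    # so channels count as walls during reflection
                    for cx, cy in _reflect_candidates(x, y, dx, dy):
                        if not geometry.in_device(cx, cy):
                            continue
                        if geometry.region_of(cx, cy).startswith("CHANNEL"):
                            continue
                        nx, ny = cx, cy
                        theta = np.arctan2(ny - y, nx - x)
                        break
                    else:
                        nx, ny = x, y  # cornered: stay put

            tr.x[f], tr.y[f] = nx, ny
            tr.regions[f] = geometry.region_of(nx, ny)
            thetas[i] = theta

    return tracks


def tracks_to_dataframe(tracks: list[GroundTruthTrack]) -> pd.DataFrame:
    """Long-format ground-truth table with the fixture CSV schema."""
    rows = []
    for tr in tracks:
        for k in range(len(tr)):
            rows.append((tr.track_id, int(tr.frames[k]), float(tr.times[k]),
                         float(tr.x[k]), float(tr.y[k]), float(tr.radius[k]),
                         tr.regions[k]))
    return pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)


def render_frames(tracks: list[GroundTruthTrack],
                  geometry: DeviceGeometry,
                  acquisition: AcquisitionParams,
                  rng: np.random.Generator | None = None) -> ImageSequence:
    """Render ground-truth tracks into a noisy fluorescence image stack.

    Each cell becomes an isotropic Gaussian blob: the nucleus (sigma =
    radius/2) convolved with the Gaussian PSF, so the blob width grows with
    cell radius. The integrated blob intensity is proportional to cell area
    (pi r^2). Blobs are summed onto a flat background; optional shot (Poisson)
    noise is applied to the full signal, then additive Gaussian read noise.
    """
    if rng is None:
        rng = np.random.default_rng(acquisition.seed + 1)
    px = acquisition.pixel_size
    H, W = geometry.image_shape
    n_frames = acquisition.n_frames
    stack = np.full((n_frames, H, W), acquisition.background_level,
                    dtype=np.float64)

    for tr in tracks:
        for k in range(len(tr)):
            f = int(tr.frames[k])
            if f >= n_frames:
                continue
            r_um = float(tr.radius[k])
            sigma = float(np.hypot(acquisition.psf_sigma, r_um / (2 * px)))
            total = acquisition.intensity_per_um2 * np.pi * r_um ** 2 / px ** 2
            amp = total / (2 * np.pi * sigma ** 2)
            cx, cy = tr.x[k] / px, tr.y[k] / px
            w = int(np.ceil(4 * sigma))
            x0, x1 = max(0, int(cx) - w), min(W, int(cx) + w + 1)
            y0, y1 = max(0, int(cy) - w), min(H, int(cy) + w + 1)
            if x0 >= x1 or y0 >= y1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            stack[f, y0:y1, x0:x1] += amp * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))

    if acquisition.shot_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    if acquisition.gaussian_sd > 0:
        stack = stack + rng.normal(0, acquisition.gaussian_sd, size=stack.shape)

    return ImageSequence(frames=stack.astype(np.float32),
                         times=acquisition.times, pixel_size=px)


def write_fixture(tracks: list[GroundTruthTrack],
                  images: ImageSequence | None,
                  out_dir: str | Path,
                  geometry: DeviceGeometry | None = None,
                  acquisition: AcquisitionParams | None = None,
                  motility: MotilityParams | None = None) -> dict:
    """Write a complete synthetic fixture and return its manifest.

    Files: ``images.tif`` (multi-frame grayscale TIFF), ``tracks.csv``
    (ground truth), ``geometry.json``, ``params.json``, ``manifest.json``.
    The fixture round-trips losslessly through :func:`read_fixture`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}

    df = tracks_to_dataframe(tracks)
    df.to_csv(out / "tracks.csv", index=False, float_format="%.6f")
    files["tracks"] = "tracks.csv"

    if images is not None:
        tifffile.imwrite(out / "images.tif", images.frames)
        files["images"] = "images.tif"

    if geometry is not None:
        (out / "geometry.json").write_text(
            json.dumps(geometry_to_dict(geometry), indent=1))
        files["geometry"] = "geometry.json"

    params = {}
    if acquisition is not None:
        params["acquisition"] = dataclasses.asdict(acquisition)
    if motility is not None:
        params["motility"] = dataclasses.asdict(motility)
    if images is not None:
        params["times_min"] = images.times.tolist()
        params["pixel_size_um"] = images.pixel_size
    (out / "params.json").write_text(json.dumps(params, indent=1))
    files["params"] = "params.json"

    manifest = {
        "files": files,
        "seed": acquisition.seed if acquisition is not None else None,
        "n_tracks": len(tracks),
        "n_frames": int(len(images)) if images is not None else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixture(out_dir: str | Path) -> dict:
    """Read back a fixture directory written by :func:`write_fixture`."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    result = {"manifest": manifest,
              "tracks": pd.read_csv(out / "tracks.csv")}
    params = json.loads((out / "params.json").read_text())
    result["params"] = params
    if "images" in manifest["files"]:
        frames = tifffile.imread(out / manifest["files"]["images"])
        result["images"] = ImageSequence(
            frames=frames, times=np.asarray(params["times_min"]),
            pixel_size=float(params["pixel_size_um"]))
    if "geometry" in manifest["files"]:
        result["geometry"] = geometry_from_dict(
            json.loads((out / "geometry.json").read_text()))
    return result
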