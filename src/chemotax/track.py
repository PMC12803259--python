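"""Frame-to-frame cell association and per-track migration measures.

Detections in successive frames are linked by nearest neighbors in a 3-D
feature space (x um, y um, area-derived third coordinate): position alone is
ambiguous when cells pass close to each other, and cell area acts as a
tie-breaking identity cue. Candidate pairs within a gating radius are
committed greedily in ascending feature distance with a deterministic
tie-break, which matches globally optimal one-to-one matching in the
low-density regime of these assays.

Per-track measures follow the standard migration-assay definitions:
velocity = trajectory path length / elapsed time (um/min), and
straightness = end-to-end distance / path length (1 = perfectly directed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um", "area_px2",
                 "region"]
TRACK_METRICS_COLUMNS = ["track_id", "velocity_um_min", "straightness",
                         "n_points", "start_region", "end_region"]


@dataclass(frozen=True)
class LinkingParams:
    """Association parameters.

    ``gate_radius`` caps the spatial displacement allowed per frame interval
    (default 20 um per 4-min frame — 5 um/min with a safety factor over the
    <= 10 um/min velocities seen in this assay). ``area_weight`` converts a
    unit difference in sqrt(area) into distance units; 0 degenerates to pure
    spatial matching. ``max_gap`` frames may be skipped by a track (default
    0: successive-frame association only). ``k`` bounds the candidate
    neighbors considered per detection.
    """

    gate_radius: float = 20.0   # um per frame interval
    area_weight: float = 1.0    # um per unit sqrt(px^2)
    max_gap: int = 0
    k: int = 3

    def __post_init__(self):
        if self.gate_radius <= 0:
            raise ParameterError("gate_radius must be positive")
        if self.area_weight < 0:
            raise ParameterError("area_weight must be >= 0")
        if self.max_gap < 0:
            raise ParameterError("max_gap must be >= 0")
        if self.k < 1:
            raise ParameterError("k must be >= 1")


def feature(x_um: float, y_um: float, area_px2: float,
            area_weight: float) -> np.ndarray:
    """Map a detection to its 3-D matching feature (x, y, w*sqrt(area))."""
    if area_px2 < 0:
        raise ParameterError("area must be >= 0")
    return np.array([x_um, y_um, area_weight * np.sqrt(area_px2)])


def _features(df: pd.DataFrame, area_weight: float) -> np.ndarray:
    return np.column_stack([
        df["x_um"].to_numpy(float),
        df["y_um"].to_numpy(float),
        area_weight * np.sqrt(df["area_px2"].to_numpy(float)),
    ])


def link_frames(dets_t: pd.DataFrame, dets_t1: pd.DataFrame,
                params: LinkingParams,
                gate_scale: float = 1.0) -> list[tuple[int, int]]:
    """One-to-one assignment between two detection tables.

    Candidates are each detection's ``k`` nearest neighbors within
    ``gate_radius * gate_scale`` (spatial gate; the area term participates
    in ranking, not gating). Pairs are committed greedily by ascending
    feature distance, ties broken by (frame-t row position, frame-t1 row
    position). Returns (row position in dets_t, row position in dets_t1)
    pairs; unmatched detections are simply absent.
    """
    n0, n1 = len(dets_t), len(dets_t1)
    if n0 == 0 or n1 == 0:
        return []
    f0 = _features(dets_t, params.area_weight)
    f1 = _features(dets_t1, params.area_weight)
    gate = params.gate_radius * gate_scale

    spatial = np.linalg.norm(f0[:, None, :2] - f1[None, :, :2], axis=2)
    dist = np.linalg.norm(f0[:, None, :] - f1[None, :, :], axis=2)

    candidates = []
    for i in range(n0):
        within = np.nonzero(spatial[i] <= gate)[0]
        if len(within) > params.k:
            order = np.argsort(dist[i, within], kind="stable")
            within = within[order[:params.k]]
        for j in within:
            candidates.append((dist[i, j], i, int(j)))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    used0: set[int] = set()
    used1: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i in used0 or j in used1:
            continue
        used0.add(i)
        used1.add(j)
        pairs.append((i, j))
    return pairs


@dataclass
class Track:
    """Ordered per-cell sequence of detections (strictly increasing frames)."""

    track_id: int
    rows: list[int] = field(default_factory=list)   # row positions in the
    # detections table, in frame order

    def __len__(self) -> int:
        return len(self.rows)


def build_tracks(detections: pd.DataFrame,
                 params: LinkingParams) -> pd.DataFrame:
    """Link detections across all frames into tracks.

    Sequential frame-to-frame linking; detections left unmatched in frame
    t+1 are first offered to tracks that last matched up to ``max_gap``
    frames earlier (gate widened proportionally to the gap), and whatever
    remains starts a new track. Every detection belongs to exactly one
    track. Returns the detections table plus a ``track_id`` column, sorted
    by (track_id, frame).
    """
    df = detections.reset_index(drop=True)
    required = {"frame", "t_min", "x_um", "y_um", "area_px2", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"detections table missing columns: {missing}")

    track_of = np.full(len(df), -1, dtype=int)
    tracks: list[Track] = []
    # open tracks: track index -> (last frame, last row position)
    open_tracks: dict[int, tuple[int, int]] = {}

    frames = sorted(df["frame"].unique())
    by_frame = {f: df.index[df["frame"] == f].to_numpy() for f in frames}

    for fpos, f in enumerate(frames):
        rows = by_frame[f]
        unmatched = list(range(len(rows)))
        if fpos > 0:
            cur = df.loc[rows]
            for gap in range(0, params.max_gap + 1):
                if not unmatched:
                    break
                prev_f = f - (gap + 1)
                # tracks whose last detection sits exactly gap+1 intervals back
                cand_tracks = [tid for tid, (lf, _) in open_tracks.items()
                               if lf == prev_f]
                if not cand_tracks:
                    continue
                prev_rows = [open_tracks[t][1] for t in cand_tracks]
                prev = df.loc[prev_rows]
                sub = cur.iloc[unmatched]
                pairs = link_frames(prev, sub, params,
                                    gate_scale=float(f - prev_f))
                newly_matched = []
                for i, j in pairs:
                    tid = cand_tracks[i]
                    row = int(rows[unmatched[j]])
                    tracks[tid].rows.append(row)
                    track_of[row] = tid
                    open_tracks[tid] = (f, row)
                    newly_matched.append(unmatched[j])
                unmatched = [u for u in unmatched if u not in newly_matched]
        for u in unmatched:
            row = int(rows[u])
            tid = len(tracks)
            tracks.append(Track(track_id=tid, rows=[row]))
            track_of[row] = tid
            open_tracks[tid] = (f, row)
        # retire tracks that can no longer be extended
        stale = [tid for tid, (lf, _) in open_tracks.items()
                 if f - lf > params.max_gap]
        for tid in stale:
            del open_tracks[tid]

    out = df.copy()
    out["track_id"] = track_of
    out = out.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return out[["track_id"] + [c for c in out.columns if c != "track_id"]]


def _path_and_net(g: pd.DataFrame) -> tuple[float, float]:
    x = g["x_um"].to_numpy(float)
    y = g["y_um"].to_numpy(float)
    steps = np.hypot(np.diff(x), np.diff(y))
    path = float(steps.sum())
    net = float(np.hypot(x[-1] - x[0], y[-1] - y[0]))
    return path, net


def track_velocity(track_points: pd.DataFrame) -> float:
    """Average velocity (um/min): trajectory path length / elapsed time.

    Uses path length, not net displacement, per the standard definition of
    distance traveled over time elapsed. Requires >= 2 detections.
    """
    if len(track_points) < 2:
        raise ParameterError("velocity undefined for single-detection tracks")
    g = track_points.sort_values("frame")
    path, _ = _path_and_net(g)
    elapsed = float(g["t_min"].iloc[-1] - g["t_min"].iloc[0])
    return path / elapsed


def straightness(track_points: pd.DataFrame) -> float:
    """End-to-end distance / trajectory path length, in [0, 1]."""
    g = track_points.sort_values("frame")
    path, net = _path_and_net(g)
    if path == 0:
        raise ParameterError("straightness undefined for zero path length")
    return net / path


def track_metrics(tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-track velocity and straightness table.

    Single-detection and zero-path tracks are excluded (their count is
    recorded in the ``attrs['n_excluded']`` of the result).
    """
    rows = []
    n_excluded = 0
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        if len(g) < 2:
            n_excluded += 1
            continue
        path, net = _path_and_net(g)
        elapsed = float(g["t_min"].iloc[-1] - g["t_min"].iloc[0])
        if path == 0 or elapsed == 0:
            n_excluded += 1
            continue
        rows.append((tid, path / elapsed, net / path, len(g),
                     g["region"].iloc[0], g["region"].iloc[-1]))
    out = pd.DataFrame(rows, columns=TRACK_METRICS_COLUMNS)
    out.attrs["n_excluded"] = n_excluded
    return out
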