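"""Device-level migration statistics and group summaries.

The four standard migration readouts of this assay are:

* **percentage migrated** — cells in a chemoattractant chamber *or* its
  migration channels at the last timepoint, divided by the cells loaded in
  the central chamber at the first timepoint, x 100;
* **rate of accumulation** — the steepest slope, over any contiguous 1-hour
  window, of the percentage of cells in the chemoattractant chamber
  (chamber only), in % per hour;
* **velocity** — per-cell path length / elapsed time (um/min);
* **straightness** — per-cell end-to-end distance / path length.

The fMLP/LTB4 migration ratio (left-% over right-%) indexes relative
responsiveness to the bacterial-mimetic versus lipid chemoattractant.
Group-level summaries report mean +/- SEM with one-way ANOVA and Tukey HSD
post hoc comparisons at alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .geometry import (CENTER, CHAMBER_LEFT, CHAMBER_RIGHT, CHANNEL_LEFT,
                       CHANNEL_RIGHT, DEVICE_REGIONS)

SIDE_REGIONS = {
    "left": (CHAMBER_LEFT, CHANNEL_LEFT),
    "right": (CHAMBER_RIGHT, CHANNEL_RIGHT),
}
SIDE_CHAMBER = {"left": CHAMBER_LEFT, "right": CHAMBER_RIGHT}

SUMMARY_COLUMNS = ["side", "percent_migrated", "accumulation_rate",
                   "rate_window_start_min", "mean_velocity",
                   "mean_straightness", "n_tracks"]


@dataclass
class CountSeries:
    """Per-frame cell counts per device region.

    ``n_total`` is the number of cells in the center loading chamber at the
    first frame — the denominator of all percentage readouts.
    """

    times: np.ndarray           # minutes, equally spaced
    counts: pd.DataFrame        # index: frame, one column per device region
    n_total: int

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 \
            else math.nan


def count_by_region(detections: pd.DataFrame) -> CountSeries:
    """Tally region-labelled detections per frame.

    Frames with zero detections produce zero rows, not gaps. Raises if
    frame 0 is absent entirely (the percentage denominator would be
    undefined).
    """
    if "frame" not in detections or "region" not in detections:
        raise ParameterError("detections need 'frame' and 'region' columns")
    if len(detections) == 0 or detections["frame"].min() != 0:
        raise ParameterError(
            "no detections at frame 0: loading-chamber denominator undefined")
    max_frame = int(detections["frame"].max())
    frames = np.arange(max_frame + 1)
    counts = (detections.groupby(["frame", "region"]).size()
              .unstack(fill_value=0)
              .reindex(index=frames, fill_value=0))
    for region in DEVICE_REGIONS:
        if region not in counts.columns:
            counts[region] = 0
    counts = counts[list(DEVICE_REGIONS)].astype(int)
    if "t_min" in detections:
        t_by_frame = detections.groupby("frame")["t_min"].first()
        if len(t_by_frame) > 1:
            # per-frame interval from the observed frames (robust to frames
            # with no detections)
            f_obs = t_by_frame.index.to_numpy(float)
            t_obs = t_by_frame.to_numpy(float)
            dt = (t_obs[-1] - t_obs[0]) / (f_obs[-1] - f_obs[0])
        else:
            dt = 1.0
        times = float(t_by_frame.iloc[0]) + (frames - frames[0]) * dt
    else:
        times = frames.astype(float)
    n_total = int(counts.loc[0, CENTER])
    return CountSeries(times=np.asarray(times, float), counts=counts,
                       n_total=n_total)


def percent_migrated(series: CountSeries, side: str) -> float:
    """Percentage of loaded cells on one side (chamber + channels) at the
    last frame."""
    chamber, channel = SIDE_REGIONS[side]
    if series.n_total <= 0:
        raise ParameterError("n_total is zero: percentage undefined")
    last = series.counts.iloc[-1]
    return float(last[chamber] + last[channel]) / series.n_total * 100.0


def accumulation_rate(series: CountSeries, side: str,
                      window: float = 60.0) -> tuple[float, float]:
    """Steepest 1-hour accumulation slope in the chemoattractant chamber.

    The chamber count (chamber only, channels excluded) is converted to a
    percentage of ``n_total``; an ordinary least-squares line is fit over
    every contiguous frame-aligned window of exactly ``window`` minutes, and
    the maximum slope (% per hour) is returned together with the start time
    (minutes) of the earliest window achieving it.
    """
    if series.n_total <= 0:
        raise ParameterError("n_total is zero: percentage undefined")
    times = series.times
    duration = times[-1] - times[0]
    if duration < window:
        raise ParameterError(
            f"recording ({duration} min) shorter than window ({window} min)")
    dt = series.frame_interval
    per_window = int(round(window / dt))  # intervals per window
    pct = (series.counts[SIDE_CHAMBER[side]].to_numpy(float)
           / series.n_total * 100.0)
    t_hours = times / 60.0

    best_slope, best_start = -np.inf, 0.0
    for s in range(len(times) - per_window):
        sl = slice(s, s + per_window + 1)
        slope = float(np.polyfit(t_hours[sl], pct[sl], 1)[0])
        if slope > best_slope + 1e-12:
            best_slope, best_start = slope, float(times[s])
    return best_slope, best_start


def migration_ratio(percent_fmlp: float,
                    percent_ltb4: float) -> float | None:
    """fMLP-side over LTB4-side migration percentage; None when the
    denominator is zero (reported as missing, never infinity)."""
    if percent_ltb4 == 0:
        return None
    return percent_fmlp / percent_ltb4


def migration_summary(tracks: pd.DataFrame,
                      track_metrics: pd.DataFrame,
                      window: float = 60.0) -> pd.DataFrame:
    """Per-side summary table of all four migration statistics.

    Velocity and straightness are averaged over tracks that *end* on the
    given side (cells that committed to that chemoattractant).
    """
    series = count_by_region(tracks)
    rows = []
    for side in ("left", "right"):
        pm = percent_migrated(series, side)
        try:
            rate, start = accumulation_rate(series, side, window=window)
        except ParameterError:
            rate, start = math.nan, math.nan
        chamber, channel = SIDE_REGIONS[side]
        m = track_metrics[track_metrics["end_region"].isin((chamber, channel))]
        rows.append((side, pm, rate, start,
                     float(m["velocity_um_min"].mean()) if len(m) else math.nan,
                     float(m["straightness"].mean()) if len(m) else math.nan,
                     len(m)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


@dataclass
class GroupSummary:
    """Mean +/- SEM per experimental group with one-way ANOVA + Tukey HSD."""

    table: pd.DataFrame          # group, n, mean, sem
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame          # group_a, group_b, diff, p_adj, significant
    excluded: list[str] = field(default_factory=list)
    alpha: float = 0.05


def group_summary(groups: dict[str, np.ndarray],
                  alpha: float = 0.05) -> GroupSummary:
    """Summarize per-device values grouped by experimental condition.

    Groups with n < 2 are excluded from inference (but flagged). With zero
    within-group variance and distinct means the F statistic diverges; this
    is reported as F = inf, p = 0 (significant).
    """
    clean, excluded = {}, []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            excluded.append(name)
        else:
            clean[name] = vals
    if len(clean) < 2:
        raise ParameterError("need >= 2 groups with n >= 2")

    rows = [(name, len(v), float(np.mean(v)),
             float(np.std(v, ddof=1) / np.sqrt(len(v))))
            for name, v in clean.items()]
    table = pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])

    arrays = list(clean.values())
    pooled_within_var = np.mean([np.var(v, ddof=1) for v in arrays])
    if pooled_within_var == 0:
        means = [np.mean(v) for v in arrays]
        degenerate_sig = len(set(means)) > 1
        f_stat = math.inf if degenerate_sig else 0.0
        p_val = 0.0 if degenerate_sig else 1.0
        names = list(clean)
        tk_rows = [(a, b, float(np.mean(clean[b]) - np.mean(clean[a])),
                    0.0 if np.mean(clean[a]) != np.mean(clean[b]) else 1.0)
                   for i, a in enumerate(names) for b in names[i + 1:]]
    else:
        f_stat, p_val = stats.f_oneway(*arrays)
        res = stats.tukey_hsd(*arrays)
        names = list(clean)
        tk_rows = []
        for i, a in enumerate(names):
            for jj in range(i + 1, len(names)):
                b = names[jj]
                tk_rows.append((a, b,
                                float(np.mean(clean[b]) - np.mean(clean[a])),
                                float(res.pvalue[i, jj])))
    tukey = pd.DataFrame(tk_rows,
                         columns=["group_a", "group_b", "diff", "p_adj"])
    tukey["significant"] = tukey["p_adj"] <= alpha
    return GroupSummary(table=table, anova_f=float(f_stat),
                        anova_p=float(p_val), tukey=tukey,
                        excluded=excluded, alpha=alpha)
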