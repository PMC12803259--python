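"""End-to-end orchestration: simulate -> detect -> track -> metrics (+ gradient).

A run is driven by a single nested configuration (YAML/JSON-friendly dict)
and a seed, writes every intermediate artifact into a run directory, and is
reproducible: the same config + seed yields byte-identical CSV outputs. The
manifest records the seed, a hash of the resolved parameters, and per-stage
input/output counts.

Motility presets for the experimental group labels (sham, sham+P188, burn,
burn+P188, by sex) are synthetic demonstration bundles: their speeds and
bias strengths are chosen so the relative ordering of simulated readouts
mirrors the qualitative trends of the assay (burn raises single-cell speed,
P188 raises chemotactic bias), not to reproduce any measured animal data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .detect import DetectionParams, detect_sequence
from .errors import ChemotaxError, ParameterError
from .geometry import make_default_geometry
from .gradient import (DiffusionSpec, MOLECULAR_WEIGHTS, diffusivity_from_mw,
                       simulate_channel_diffusion)
from .metrics import migration_summary
from .synthdata import (AcquisitionParams, MotilityParams, render_frames,
                        simulate_tracks, write_fixture)
from .track import LinkingParams, build_tracks, track_metrics

log = logging.getLogger("chemotax")

#: Synthetic motility presets per (group, sex). Speeds (um/min) follow the
#: assay's reported single-cell velocity scale; bias_right encodes the
#: LTB4-side chemotactic strength. Demo scaffolding only.
GROUP_PRESETS: dict[tuple[str, str], dict] = {
    ("sham", "male"):        {"speed_mean": 6.8, "bias_right": 0.13},
    ("sham", "female"):      {"speed_mean": 6.1, "bias_right": 0.18},
    ("sham+P188", "male"):   {"speed_mean": 7.5, "bias_right": 0.15},
    ("sham+P188", "female"): {"speed_mean": 6.9, "bias_right": 0.29},
    ("burn", "male"):        {"speed_mean": 9.9, "bias_right": 0.11},
    ("burn", "female"):      {"speed_mean": 9.6, "bias_right": 0.07},
    ("burn+P188", "male"):   {"speed_mean": 7.6, "bias_right": 0.18},
    ("burn+P188", "female"): {"speed_mean": 6.7, "bias_right": 0.23},
}


def default_run_config() -> dict:
    """A small, fast demonstration configuration."""
    return {
        "geometry": {},
        "acquisition": {},
        "motility": {},
        "detection": {},
        "linking": {},
        "metrics": {"accumulation_window_min": 60.0},
        "gradient": {"species": ["fMLP", "LTB4"],
                     "reference": ["dextran", 50.0],
                     "times_s": [60.0, 300.0, 900.0]},
        "seed": 0,
    }


def _resolve(config: dict, seed: int | None = None) -> dict:
    """Merge a user config over defaults and resolve group presets."""
    cfg = default_run_config()
    for key, val in (config or {}).items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    motility = dict(cfg.get("motility") or {})
    group, sex = motility.pop("group", None), motility.pop("sex", None)
    if group is not None:
        preset = GROUP_PRESETS.get((group, sex or "female"))
        if preset is None:
            raise ParameterError(f"unknown group preset ({group}, {sex})")
        cfg["motility"] = {**preset, **motility}
    else:
        cfg["motility"] = motility
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


def validate_config(config: dict) -> dict:
    """Check every sub-config invariant; never raises on content.

    Returns ``{"valid": bool, "violations": [str, ...]}`` where each
    violation names the offending field (dotted path).
    """
    violations: list[str] = []
    try:
        cfg = _resolve(config)
    except ChemotaxError as exc:
        return {"valid": False, "violations": [f"motility.group: {exc}"]}

    acq = cfg["acquisition"]
    if float(acq.get("frame_interval", 4.0)) <= 0:
        violations.append("acquisition.frame_interval: must be positive")
    if float(acq.get("duration", 240.0)) < float(acq.get("frame_interval", 4.0)):
        violations.append("acquisition.duration: must be >= frame_interval")
    try:
        if not violations:
            AcquisitionParams(**{**acq, "seed": 0})
    except (ChemotaxError, TypeError) as exc:
        violations.append(f"acquisition: {exc}")
    try:
        geom = make_default_geometry(cfg["geometry"])
        problems = geom.validate()
        violations += [f"geometry: {p}" for p in problems]
    except (ChemotaxError, TypeError) as exc:
        violations.append(f"geometry: {exc}")
    for section, cls in (("motility", MotilityParams),
                         ("detection", DetectionParams),
                         ("linking", LinkingParams)):
        try:
            cls(**cfg[section])
        except (ChemotaxError, TypeError) as exc:
            violations.append(f"{section}: {exc}")
    return {"valid": not violations, "violations": violations}


def _param_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Execute all stages, writing every artifact into ``out_dir``.

    Returns the run directory. Raises on the first failing stage (partial
    artifacts are retained on disk).
    """
    cfg = _resolve(config or {}, seed=seed)
    report = validate_config(cfg)
    if not report["valid"]:
        raise ParameterError("invalid config: " + "; ".join(report["violations"]))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_seed = int(cfg["seed"])
    files: dict[str, str] = {}
    counts: dict[str, int] = {}

    # -- simulate ---------------------------------------------------------
    geometry = make_default_geometry(cfg["geometry"])
    acquisition = AcquisitionParams(**{**cfg["acquisition"], "seed": run_seed})
    motility = MotilityParams(**cfg["motility"])
    log.info("simulate: %d cells, %d frames", motility.n_cells,
             acquisition.n_frames)
    gt_tracks = simulate_tracks(geometry, motility, acquisition)
    images = render_frames(gt_tracks, geometry, acquisition)
    write_fixture(gt_tracks, images, out, geometry=geometry,
                  acquisition=acquisition, motility=motility)
    files.update(images="images.tif", ground_truth="tracks.csv",
                 geometry="geometry.json", params="params.json")
    counts["simulated_cells"] = motility.n_cells
    counts["frames"] = acquisition.n_frames

    # -- detect -----------------------------------------------------------
    detection = DetectionParams(**cfg["detection"])
    detections = detect_sequence(images, detection, geometry)
    detections.to_csv(out / "detections.csv", index=False,
                      float_format="%.6f")
    files["detections"] = "detections.csv"
    counts["detections"] = len(detections)
    log.info("detect: %d detections over %d frames", len(detections),
             acquisition.n_frames)

    # -- track ------------------------------------------------------------
    linking = LinkingParams(**cfg["linking"])
    tracks = build_tracks(detections, linking)
    tracks[["track_id", "frame", "t_min", "x_um", "y_um", "area_px2",
            "region"]].to_csv(out / "linked_tracks.csv", index=False,
                              float_format="%.6f")
    tmetrics = track_metrics(tracks)
    tmetrics.to_csv(out / "trackmetrics.csv", index=False,
                    float_format="%.6f")
    files["tracks"] = "linked_tracks.csv"
    files["track_metrics"] = "trackmetrics.csv"
    counts["tracks"] = int(tracks["track_id"].nunique())
    counts["tracks_excluded_from_metrics"] = tmetrics.attrs["n_excluded"]
    log.info("track: %d tracks (%d excluded from per-track metrics)",
             counts["tracks"], counts["tracks_excluded_from_metrics"])

    # -- metrics ----------------------------------------------------------
    window = float(cfg["metrics"].get("accumulation_window_min", 60.0))
    summary = migration_summary(tracks, tmetrics, window=window)
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6f")
    files["summary"] = "summary.csv"

    # -- gradient ---------------------------------------------------------
    gcfg = cfg.get("gradient")
    if gcfg:
        ref_name, ref_d = gcfg.get("reference", ["dextran", 50.0])
        prof_rows, fits = [], {}
        for sp in gcfg.get("species", []):
            mw = MOLECULAR_WEIGHTS[sp]
            spec = DiffusionSpec(
                species=sp, molecular_weight=mw,
                diffusivity=diffusivity_from_mw(
                    mw, (MOLECULAR_WEIGHTS[ref_name], float(ref_d))),
                channel_length=geometry.channels[0].rect.width
                if geometry.channels else 500.0)
            profs = simulate_channel_diffusion(spec, gcfg["times_s"])
            for p in profs:
                for pos, val in zip(p.positions, p.values):
                    prof_rows.append((sp, p.time, pos, val))
            last = profs[-1]
            fits[sp] = {"time_s": last.time, "slope": last.slope,
                        "intercept": last.intercept,
                        "r_squared": last.r_squared}
        pd.DataFrame(prof_rows, columns=["species", "time_s", "position_um",
                                         "value"]).to_csv(
            out / "gradient_profiles.csv", index=False, float_format="%.6f")
        (out / "gradient_fits.json").write_text(json.dumps(fits, indent=1))
        files["gradient_profiles"] = "gradient_profiles.csv"
        files["gradient_fits"] = "gradient_fits.json"

    manifest = {
        "version": __version__,
        "seed": run_seed,
        "param_hash": _param_hash(cfg),
        "config": cfg,
        "files": files,
        "counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s", out)
    return out
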