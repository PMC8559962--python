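"""Run configuration and the staged analysis pipeline.

A :class:`RunConfig` (YAML-serializable) carries acquisition, detection,
tracking and metric parameters plus the seed and output directory.  The
pipeline chains simulate -> detect -> track -> analyze -> classify; each
stage writes its CSV/JSON artifact into the output directory and later
stages fail with a :class:`DependencyError` when an upstream artifact is
missing.  Identical config + seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect as _detect
from . import metrics as _metrics
from . import nucleus as _nucleus
from . import simulate as _simulate
from . import tracking as _tracking
from .classify import classify_decluster_program
from .errors import DependencyError
from .evaluate import lineage_from_tracks
from .io import Movie, config_hash, read_movie, write_movie, write_table

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "detect", "track", "analyze", "classify")

log = logging.getLogger("chromotrace")


@dataclass
class RunConfig:
    out_dir: str = "chromotrace_run"
    seed: int = 0
    movie_path: str | None = None          # input movie when not simulating
    # simulation
    program: str = "canonical"
    stage_durations_s: tuple = (30.0,) * 7
    n_frames: int = 48
    frame_interval_s: float = 5.0
    z_planes: int = 29
    z_spacing_um: float = 0.8
    xy_pixel_um: float = 0.25
    ny: int = 96
    nx: int = 96
    nucleus_radius_um: float = 4.0
    mode: str = "wildtype"
    # detection
    dot_channel: int = 1
    nuclear_channel: int = 0
    estimated_xy_diameter_um: float = 0.5
    quality_threshold: float | None = None
    # tracking
    max_step_um: float = 0.6
    max_gap: int = 2
    motion_memory: float = 0.8
    association_radius_um: float = 2.2
    # metrics
    debounce_frames: int = 2
    min_separation_um: float = 1.0
    min_duration_frames: int = 3

    def as_dict(self):
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage_durations_s" in doc:
            doc["stage_durations_s"] = tuple(float(x) for x in doc["stage_durations_s"])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = self.as_dict()
        doc["stage_durations_s"] = list(doc["stage_durations_s"])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _setup_logging(out: Path, verbose: bool):
    log.setLevel(logging.DEBUG if verbose else logging.INFO)
    log.handlers.clear()
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(out / "run.log", mode="a")):
        h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(h)


def _require(path: Path, stage: str, needed_by: str):
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' requires output of stage '{stage}' "
            f"({path.name} not found in {path.parent})")


def run_pipeline(config: RunConfig, stages=STAGES, verbose=False) -> dict:
    """Run the requested pipeline stages; returns paths of written artifacts."""
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, verbose)
    # the hash embedded in outputs covers the analysis parameters only, so
    # the same run in a different directory is byte-identical
    cfg = {k: v for k, v in config.as_dict().items()
           if k not in ("out_dir", "movie_path")}
    log.info("run config hash %s; stages %s; seed %d",
             config_hash(cfg), stages, config.seed)
    config.to_yaml(out / "config.yaml")
    artifacts = {}

    movie_path = out / "movie.ome.tif"
    spots_path = out / "spots.csv"
    tracks_path = out / "tracks.csv"
    nucleus_path = out / "nucleus.csv"
    drift_path = out / "drift.csv"

    if "simulate" in stages:
        acq = _simulate.AcquisitionConfig(
            n_frames=config.n_frames, frame_interval_s=config.frame_interval_s,
            z_planes=config.z_planes, z_spacing_um=config.z_spacing_um,
            xy_pixel_um=config.xy_pixel_um, ny=config.ny, nx=config.nx)
        schedule = _simulate.simulate_decluster_schedule(
            config.program, config.stage_durations_s, seed=config.seed)
        motion = _simulate.MotionConfig(seed=config.seed)
        movie, gt = _simulate.simulate_movie(
            schedule=schedule, motion=motion, acq=acq, mode=config.mode,
            nucleus_radius_um=config.nucleus_radius_um)
        write_movie(movie, movie_path)
        write_table(gt.dots, out / "truth_dots.csv",
                    units={"z_um": "µm", "y_um": "µm", "x_um": "µm",
                           "time_s": "s"}, config=cfg)
        write_table(gt.events, out / "truth_events.csv", config=cfg)
        write_table(gt.drift, out / "truth_drift.csv", config=cfg)
        write_table(gt.nucleus, out / "truth_nucleus.csv", config=cfg)
        artifacts["movie"] = movie_path
        log.info("simulated %d frames (%s program)", movie.n_frames,
                 config.program)

    if "detect" in stages:
        src = Path(config.movie_path) if config.movie_path else movie_path
        _require(src, "simulate", "detect")
        movie = read_movie(src)
        rows = []
        nuc_rows = []
        for t in range(movie.n_frames):
            spots = _detect.detect_spots(
                movie.frame(t, config.dot_channel), movie.spacing,
                config.estimated_xy_diameter_um,
                quality_threshold=config.quality_threshold,
                frame_index=t, channel=config.dot_channel)
            rows.extend(dict(frame=t, channel=s.channel, z_um=s.z, y_um=s.y,
                             x_um=s.x, intensity=s.integrated_intensity,
                             quality=s.quality) for s in spots)
            nuc = _nucleus.segment_nucleus(movie.frame(t, config.nuclear_channel),
                                           movie.spacing)
            nuc_rows.append(dict(frame=t, cz_um=nuc.centroid_um[0],
                                 cy_um=nuc.centroid_um[1],
                                 cx_um=nuc.centroid_um[2],
                                 diameter_um=nuc.equivalent_diameter_um))
        cols = ["frame", "channel", "z_um", "y_um", "x_um", "intensity",
                "quality"]
        write_table(pd.DataFrame(rows, columns=cols), spots_path,
                    units={"z_um": "µm", "y_um": "µm", "x_um": "µm"},
                    config=cfg)
        write_table(pd.DataFrame(nuc_rows), nucleus_path,
                    units={"diameter_um": "µm"}, config=cfg)
        artifacts["spots"] = spots_path
        artifacts["nucleus"] = nucleus_path
        log.info("detected %d spots over %d frames", len(rows), movie.n_frames)

    if "track" in stages:
        _require(spots_path, "detect", "track")
        _require(nucleus_path, "detect", "track")
        spots_df = pd.read_csv(spots_path, comment="#")
        nuc_df = pd.read_csv(nucleus_path, comment="#")
        spots = [
            _detect.SpotRecord(frame=int(r.frame), channel=int(r.channel),
                               position_um=np.array([r.z_um, r.y_um, r.x_um]),
                               estimated_diameter_um=config.estimated_xy_diameter_um,
                               integrated_intensity=float(r.intensity),
                               quality=float(r.quality))
            for r in spots_df.itertuples()]
        tracks = _tracking.link_tracks(spots, max_gap=config.max_gap,
                                       max_step=config.max_step_um,
                                       motion_memory=config.motion_memory)
        centroids = {int(r.frame): np.array([r.cz_um, r.cy_um, r.cx_um])
                     for r in nuc_df.itertuples()}
        tracks, drift = _tracking.correct_drift(tracks, centroids)
        _tracking.detect_splits_fusions(
            tracks, association_radius=config.association_radius_um)
        write_table(_tracking.tracks_to_table(tracks), tracks_path,
                    units={c: "µm" for c in
                           ("z_um", "y_um", "x_um", "z_corr_um", "y_corr_um",
                            "x_corr_um")}, config=cfg)
        write_table(pd.DataFrame({"frame": drift.frames,
                                  "dz_um": drift.drift_um[:, 0],
                                  "dy_um": drift.drift_um[:, 1],
                                  "dx_um": drift.drift_um[:, 2]}),
                    drift_path, units={"dz_um": "µm"}, config=cfg)
        artifacts["tracks"] = tracks_path
        artifacts["drift"] = drift_path
        log.info("linked %d tracks", len(tracks))

    if "analyze" in stages or "classify" in stages:
        _require(tracks_path, "track", "analyze/classify")
        tracks_df = pd.read_csv(tracks_path, comment="#")
        tracks = _tracks_from_table(tracks_df)

    if "analyze" in stages:
        counts = tracks_df.groupby("frame")["track_id"].nunique()
        stage_series = _metrics.dot_stage_intervals(
            counts, config.frame_interval_s, debounce=config.debounce_frames)
        iv = pd.DataFrame([dataclasses.asdict(i) for i in stage_series.intervals])
        write_table(iv, out / "stage_intervals.csv",
                    units={"duration_s": "s"}, config=cfg)
        mean, sd, n = _tracking.velocity_summary(tracks, config.frame_interval_s)
        write_table(pd.DataFrame([{"mean_speed_um_s": mean, "sd_um_s": sd,
                                   "n_intervals": n}]),
                    out / "velocities.csv",
                    units={"mean_speed_um_s": "µm/s"}, config=cfg)
        artifacts["stage_intervals"] = out / "stage_intervals.csv"
        artifacts["velocities"] = out / "velocities.csv"
        log.info("mean speed %.4f µm/s over %d intervals", mean, n)

    if "classify" in stages:
        for tr in tracks:  # re-derive lineage from scratch
            tr.parent_id = None
            tr.child_ids = []
        splits, _fusions = _tracking.detect_splits_fusions(
            tracks, association_radius=config.association_radius_um)
        nodes = lineage_from_tracks(tracks, splits)
        call = classify_decluster_program(nodes)
        summary = {
            "program": call.program,
            "identity_map": call.identity_map,
            "split_assignments": [[int(f), lab] for f, lab in
                                  call.split_assignments],
            "notes": call.notes,
            "config_hash": config_hash(cfg),
        }
        with open(out / "classification.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        artifacts["classification"] = out / "classification.json"
        log.info("program call: %s", call.program)

    return artifacts


def _tracks_from_table(df: pd.DataFrame):
    tracks = []
    for tid, grp in df.groupby("track_id"):
        grp = grp.sort_values("frame")
        tr = _tracking.Track(track_id=int(tid))
        tr.frames = [int(f) for f in grp["frame"]]
        tr.positions_um = [np.array(p) for p in
                           grp[["z_um", "y_um", "x_um"]].to_numpy()]
        tr.corrected_um = [np.array(p) for p in
                           grp[["z_corr_um", "y_corr_um", "x_corr_um"]].to_numpy()]
        tr.intensities = [float(v) for v in grp["intensity"]]
        tr.qualities = [np.nan] * len(tr.frames)
        parent = int(grp["parent_id"].iloc[0])
        tr.parent_id = None if parent < 0 else parent
        tracks.append(tr)
    return tracks
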