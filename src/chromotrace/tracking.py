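"""Detection linking, drift correction, velocities and split/fusion calling.

Detections are linked frame to frame with a constant-velocity (first-order
autoregressive) motion prediction: each active track predicts its next
position as ``last + motion_memory * last_displacement`` and the per-frame
assignment is solved as an optimal bipartite matching on Euclidean costs
gated by ``max_step``; unmatched detections open new tracks and tracks may
bridge up to ``max_gap`` missing frames.  Whole-nucleus translational drift
is removed by subtracting the nucleus-centroid displacement, after which
per-interval speeds and split/fusion events (with intensity partition
fractions) are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import SpotRecord

__all__ = ["Track", "SplitEvent", "FusionEvent", "DriftSeries", "link_tracks",
           "correct_drift", "compute_velocities", "velocity_summary",
           "detect_splits_fusions", "tracks_to_table", "apply_edits"]


@dataclass
class Track:
    track_id: int
    frames: list = field(default_factory=list)
    positions_um: list = field(default_factory=list)   # image frame
    intensities: list = field(default_factory=list)
    qualities: list = field(default_factory=list)
    parent_id: int | None = None
    child_ids: list = field(default_factory=list)
    corrected_um: list | None = None                   # nucleus frame

    def __len__(self):
        return len(self.frames)

    @property
    def start(self):
        return self.frames[0]

    @property
    def end(self):
        return self.frames[-1]

    def positions(self, corrected=True) -> np.ndarray:
        src = self.corrected_um if (corrected and self.corrected_um is not None) \
            else self.positions_um
        return np.asarray(src, dtype=float)

    def position_at(self, frame: int, corrected=True):
        try:
            i = self.frames.index(frame)
        except ValueError:
            return None
        return self.positions(corrected)[i]

    def intensity_at(self, frame: int):
        try:
            return self.intensities[self.frames.index(frame)]
        except ValueError:
            return None

    def mean_intensity(self, frames=None) -> float:
        if frames is None:
            return float(np.mean(self.intensities))
        vals = [self.intensity_at(f) for f in frames]
        vals = [v for v in vals if v is not None]
        return float(np.mean(vals)) if vals else np.nan


@dataclass
class SplitEvent:
    frame: int
    parent_id: int
    child1_id: int     # newly opened track
    child2_id: int     # continuing parent branch
    partition_fraction: float
    ambiguous: bool = False

    def __post_init__(self):
        if not 0.0 < self.partition_fraction < 1.0:
            raise ValueError("partition_fraction must be in (0, 1)")


@dataclass
class FusionEvent:
    frame: int
    track1_id: int     # terminated track
    track2_id: int     # surviving track
    ambiguous: bool = False


@dataclass
class DriftSeries:
    frames: np.ndarray
    drift_um: np.ndarray   # (n, 3); zero at frame 0

    def at(self, frame: int) -> np.ndarray:
        i = int(np.searchsorted(self.frames, frame))
        return self.drift_um[min(i, len(self.frames) - 1)]


def _spots_by_frame(spots) -> dict[int, list[SpotRecord]]:
    by = {}
    for s in spots:
        by.setdefault(s.frame, []).append(s)
    # deterministic within-frame order regardless of input order
    for f in by:
        by[f].sort(key=lambda s: (s.z, s.y, s.x))
    return by


def link_tracks(
    spots,
    max_gap: int = 1,
    max_step: float = 1.0,
    motion_memory: float = 0.8,
) -> list[Track]:
    """Link spot detections into tracks.

    Parameters
    ----------
    spots : iterable of SpotRecord (any order; sorted internally).
    max_gap : frames a track may survive without a detection.
    max_step : gating radius (um) between prediction and candidate.
    motion_memory : weight of the previous displacement in the prediction
        (0 = nearest-neighbour, 1 = full constant-velocity extrapolation).
    """
    if not 0.0 <= motion_memory <= 1.0:
        raise ValueError("motion_memory must be in [0, 1]")
    by_frame = _spots_by_frame(spots)
    if not by_frame:
        return []
    frames = range(min(by_frame), max(by_frame) + 1)
    tracks: list[Track] = []
    active: list[Track] = []

    def predict(tr: Track, frame: int) -> np.ndarray:
        pos = np.asarray(tr.positions_um[-1], dtype=float)
        if len(tr) >= 2:
            disp = pos - np.asarray(tr.positions_um[-2], dtype=float)
            gap = tr.frames[-1] - tr.frames[-2]
            pos = pos + motion_memory * disp / gap * (frame - tr.frames[-1])
        return pos

    BIG = 1e6
    for f in frames:
        cands = by_frame.get(f, [])
        assigned_spots: set[int] = set()
        if active and cands:
            cost = np.full((len(active), len(cands)), BIG)
            for i, tr in enumerate(active):
                pred = predict(tr, f)
                for j, s in enumerate(cands):
                    d = float(np.linalg.norm(pred - s.position_um))
                    if d <= max_step * (f - tr.frames[-1]):
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] >= BIG:
                    continue
                tr, s = active[i], cands[j]
                tr.frames.append(f)
                tr.positions_um.append(np.asarray(s.position_um, dtype=float))
                tr.intensities.append(s.integrated_intensity)
                tr.qualities.append(s.quality)
                assigned_spots.add(j)
        for j, s in enumerate(cands):
            if j in assigned_spots:
                continue
            tr = Track(track_id=len(tracks))
            tr.frames.append(f)
            tr.positions_um.append(np.asarray(s.position_um, dtype=float))
            tr.intensities.append(s.integrated_intensity)
            tr.qualities.append(s.quality)
            tracks.append(tr)
            active.append(tr)
        active = [tr for tr in active if f - tr.frames[-1] <= max_gap]
    return tracks


def correct_drift(tracks, nucleus_centroids) -> tuple[list, DriftSeries]:
    """Move track positions into the nucleus frame.

    ``nucleus_centroids`` maps frame -> centroid (um, image frame) or is a
    DataFrame with columns frame, cz_um, cy_um, cx_um.  Missing frames are
    linearly interpolated (with a warning).  Positions become
    ``position - (centroid_t - centroid_0)``.
    """
    if isinstance(nucleus_centroids, pd.DataFrame):
        nucleus_centroids = {
            int(r["frame"]): np.array([r["cz_um"], r["cy_um"], r["cx_um"]])
            for _, r in nucleus_centroids.iterrows()}
    frames_needed = sorted({f for tr in tracks for f in tr.frames})
    if not frames_needed:
        return tracks, DriftSeries(np.array([0]), np.zeros((1, 3)))
    have = sorted(nucleus_centroids)
    missing = [f for f in frames_needed if f not in nucleus_centroids]
    if missing:
        warnings.warn(f"interpolating nucleus centroid at frames {missing}")
    lo, hi = min(frames_needed + have), max(frames_needed + have)
    all_frames = np.arange(lo, hi + 1)
    cents = np.empty((len(all_frames), 3))
    have_arr = np.asarray(have)
    have_pos = np.asarray([nucleus_centroids[f] for f in have], dtype=float)
    for ax in range(3):
        cents[:, ax] = np.interp(all_frames, have_arr, have_pos[:, ax])
    drift = cents - cents[0]
    idx = {int(f): i for i, f in enumerate(all_frames)}
    for tr in tracks:
        tr.corrected_um = [
            np.asarray(p, dtype=float) - drift[idx[f]]
            for f, p in zip(tr.frames, tr.positions_um)]
    return tracks, DriftSeries(all_frames, drift)


def compute_velocities(track: Track, frame_interval_s: float) -> np.ndarray:
    """Per-interval speeds (um/s) of a drift-corrected track."""
    if len(track) < 2:
        return np.array([])
    pos = track.positions(corrected=True)
    gaps = np.diff(np.asarray(track.frames))
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    return steps / (gaps * frame_interval_s)


def velocity_summary(tracks, frame_interval_s: float) -> tuple[float, float, int]:
    """Pooled mean +/- SD speed over all intervals of all tracks."""
    speeds = np.concatenate(
        [compute_velocities(tr, frame_interval_s) for tr in tracks]
        or [np.array([])])
    if speeds.size == 0:
        return np.nan, np.nan, 0
    return float(speeds.mean()), float(speeds.std(ddof=1)) if speeds.size > 1 else 0.0, \
        int(speeds.size)


def _windowed_intensity(track: Track, frames) -> float:
    vals = [track.intensity_at(f) for f in frames]
    vals = [v for v in vals if v is not None]
    return float(np.mean(vals)) if vals else np.nan


def detect_splits_fusions(
    tracks,
    association_radius: float = 2.2,
    intensity_tolerance: float = 0.5,
    window: int = 3,
) -> tuple[list[SplitEvent], list[FusionEvent]]:
    """Call split and fusion events from track starts/ends and intensities.

    A split: a track opens at frame f within ``association_radius`` of a
    track present at f-1 and f whose intensity drops between the flanking
    frames by an amount commensurate with the newcomer's intensity
    (relative mismatch <= ``intensity_tolerance``).  Intensities are
    averaged over up to ``window`` frames on each side, since a splitting
    dot sheds its product gradually while the two remain unresolved.  A
    fusion is the time reverse.  Multiple equally valid parents flag the
    event ambiguous.  Lineage links are written onto the tracks.
    """
    splits, fusions = [], []
    for tr in sorted(tracks, key=lambda t: (t.start, t.track_id)):
        f = tr.start
        if f == 0 or tr.parent_id is not None:
            continue
        pos0 = tr.positions(corrected=True)[0]
        i_child = _windowed_intensity(tr, range(f, f + window))
        candidates = []
        for other in tracks:
            if other.track_id == tr.track_id:
                continue
            p_pre = other.position_at(f - 1)
            p_post = other.position_at(f)
            if p_pre is None or p_post is None:
                continue
            if np.linalg.norm(p_post - pos0) > association_radius and \
               np.linalg.norm(p_pre - pos0) > association_radius:
                continue
            i_pre = _windowed_intensity(other, range(f - window, f))
            i_post = _windowed_intensity(other, range(f, f + window))
            drop = i_pre - i_post
            mismatch = abs(drop - i_child) / max(i_pre, 1e-12)
            candidates.append((mismatch, np.linalg.norm(p_post - pos0), other))
        ok = [c for c in candidates if c[0] <= intensity_tolerance]
        if not ok:
            continue
        ok.sort(key=lambda c: (c[0], c[1], c[2].track_id))
        ambiguous = len(ok) > 1 and abs(ok[0][0] - ok[1][0]) < 0.05
        parent = ok[0][2]
        i_post = _windowed_intensity(parent, range(f, f + window))
        pf = i_child / (i_child + i_post) if (i_child + i_post) > 0 else 0.5
        pf = float(np.clip(pf, 1e-6, 1 - 1e-6))
        tr.parent_id = parent.track_id
        parent.child_ids.append(tr.track_id)
        splits.append(SplitEvent(frame=f, parent_id=parent.track_id,
                                 child1_id=tr.track_id,
                                 child2_id=parent.track_id,
                                 partition_fraction=pf, ambiguous=ambiguous))

    last_frame = max((tr.end for tr in tracks), default=0)
    for tr in tracks:
        f = tr.end
        if f >= last_frame:
            continue
        pos_end = tr.positions(corrected=True)[-1]
        candidates = []
        for other in tracks:
            if other.track_id == tr.track_id:
                continue
            p_pre = other.position_at(f)
            p_post = other.position_at(f + 1)
            if p_pre is None or p_post is None:
                continue
            if np.linalg.norm(p_pre - pos_end) > association_radius:
                continue
            i_pre = other.intensity_at(f)
            i_post = other.intensity_at(f + 1)
            gain = i_post - i_pre
            mismatch = abs(gain - tr.intensities[-1]) / max(i_post, 1e-12)
            candidates.append((mismatch, np.linalg.norm(p_pre - pos_end), other))
        ok = [c for c in candidates if c[0] <= intensity_tolerance]
        if not ok:
            continue
        ok.sort(key=lambda c: (c[0], c[1], c[2].track_id))
        ambiguous = len(ok) > 1 and abs(ok[0][0] - ok[1][0]) < 0.05
        fusions.append(FusionEvent(frame=f + 1, track1_id=tr.track_id,
                                   track2_id=ok[0][2].track_id,
                                   ambiguous=ambiguous))
    return splits, fusions


def tracks_to_table(tracks) -> pd.DataFrame:
    """One row per track per frame: raw and drift-corrected positions."""
    rows = []
    for tr in tracks:
        corr = tr.positions(corrected=True)
        raw = tr.positions(corrected=False)
        for i, f in enumerate(tr.frames):
            rows.append(dict(
                track_id=tr.track_id, frame=f,
                z_um=raw[i][0], y_um=raw[i][1], x_um=raw[i][2],
                z_corr_um=corr[i][0], y_corr_um=corr[i][1], x_corr_um=corr[i][2],
                intensity=tr.intensities[i],
                parent_id=-1 if tr.parent_id is None else tr.parent_id,
            ))
    cols = ["track_id", "frame", "z_um", "y_um", "x_um",
            "z_corr_um", "y_corr_um", "x_corr_um", "intensity", "parent_id"]
    return pd.DataFrame(rows, columns=cols)


def apply_edits(tracks, edits: pd.DataFrame) -> list:
    """Apply a deterministic batch of manual corrections to tracks.

    ``edits`` rows have columns op (add_spot | delete_spot | cut | join),
    track_id, frame, and for add_spot z_um/y_um/x_um/intensity; rows are
    applied in file order.
    """
    by_id = {tr.track_id: tr for tr in tracks}
    next_id = max(by_id, default=-1) + 1
    for _, row in edits.iterrows():
        op = row["op"]
        tr = by_id.get(int(row["track_id"]))
        if tr is None:
            raise KeyError(f"unknown track {row['track_id']}")
        f = int(row["frame"])
        if op == "add_spot":
            pos = np.array([row["z_um"], row["y_um"], row["x_um"]], dtype=float)
            i = int(np.searchsorted(tr.frames, f))
            if f in tr.frames:
                raise ValueError(f"track {tr.track_id} already has frame {f}")
            tr.frames.insert(i, f)
            tr.positions_um.insert(i, pos)
            tr.intensities.insert(i, float(row.get("intensity", np.nan)))
            tr.qualities.insert(i, np.nan)
            if tr.corrected_um is not None:
                tr.corrected_um.insert(i, pos)
        elif op == "delete_spot":
            i = tr.frames.index(f)
            for lst in (tr.frames, tr.positions_um, tr.intensities, tr.qualities):
                del lst[i]
            if tr.corrected_um is not None:
                del tr.corrected_um[i]
        elif op == "cut":
            i = int(np.searchsorted(tr.frames, f))
            new = Track(track_id=next_id)
            next_id += 1
            new.frames = tr.frames[i:]
            new.positions_um = tr.positions_um[i:]
            new.intensities = tr.intensities[i:]
            new.qualities = tr.qualities[i:]
            if tr.corrected_um is not None:
                new.corrected_um = tr.corrected_um[i:]
                tr.corrected_um = tr.corrected_um[:i]
            tr.frames = tr.frames[:i]
            tr.positions_um = tr.positions_um[:i]
            tr.intensities = tr.intensities[:i]
            tr.qualities = tr.qualities[:i]
            tracks.append(new)
            by_id[new.track_id] = new
        elif op == "join":
            other = by_id[int(row["other_track_id"])]
            if other.frames and tr.frames and other.frames[0] <= tr.frames[-1]:
                raise ValueError("join requires disjoint, ordered tracks")
            tr.frames += other.frames
            tr.positions_um += other.positions_um
            tr.intensities += other.intensities
            tr.qualities += other.qualities
            if tr.corrected_um is not None and other.corrected_um is not None:
                tr.corrected_um += other.corrected_um
            tracks.remove(other)
            del by_id[other.track_id]
        else:
            raise ValueError(f"unknown edit op {op!r}")
    return [tr for tr in tracks if len(tr) > 0]
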