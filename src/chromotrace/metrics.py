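"""Per-cell dynamic readouts derived from tracks.

Covers the quantitative summaries used to characterize territory formation:
dot-count stage intervals with censoring at the observation window, dot
intensity ratios, pairwise separation series with the single-spot
zero-encoding, stretch-episode extraction, radial-position summaries over
the first frames of imaging, and two-sample group comparison (two-tailed
Student t test with the conventional significance stars).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StageInterval", "DotStageSeries", "StretchEpisode",
    "dot_stage_intervals", "intensity_ratio_report", "pair_separation",
    "separation_series", "stretch_episodes", "radial_summary",
    "compare_groups", "significance_stars",
]


@dataclass
class StageInterval:
    k: int                  # dot count of the stage
    start_frame: int
    end_frame: int          # inclusive
    duration_s: float
    censoring: str          # complete | left_censored | right_censored | both_censored

    @property
    def is_minimal_duration(self) -> bool:
        return self.censoring != "complete"


@dataclass
class DotStageSeries:
    counts: pd.Series       # per-frame dot count (index = frame)
    intervals: list
    frame_interval_s: float


@dataclass
class StretchEpisode:
    start_frame: int
    end_frame: int          # inclusive
    max_separation_um: float
    outcome: str            # relaxed | definitive_split


def _debounce(counts: np.ndarray, debounce: int) -> np.ndarray:
    """Bridge transient count dips shorter than ``debounce`` frames.

    A maximal run of identical counts strictly shorter than ``debounce``
    whose two neighbours have the same, higher count (a transient fusion)
    is replaced by that neighbour count.
    """
    if debounce <= 0:
        return counts
    counts = counts.copy()
    n = len(counts)
    i = 0
    while i < n:
        j = i
        while j < n and counts[j] == counts[i]:
            j += 1
        run_len = j - i
        if 0 < i and j < n and run_len < debounce \
                and counts[i - 1] == counts[j] and counts[j] > counts[i]:
            counts[i:j] = counts[j]
        i = j
    return counts


def dot_stage_intervals(
    counts,
    frame_interval_s: float,
    debounce: int = 2,
) -> DotStageSeries:
    """Maximal constant-dot-count runs as stage intervals with censoring.

    Runs touching the start (end) of the observation window are left
    (right) censored and their durations are minimal durations, i.e. lower
    bounds.  A transient fusion dip shorter than ``debounce`` frames is
    bridged before run-length encoding.  Duration of a run of n frames is
    ``n * frame_interval_s``.
    """
    if isinstance(counts, pd.Series):
        frames = counts.index.to_numpy()
        vals = counts.to_numpy()
    else:
        vals = np.asarray(counts, dtype=int)
        frames = np.arange(len(vals))
    if np.any(vals < 0):
        raise ValueError("dot counts must be >= 0")
    vals = _debounce(vals, debounce)
    intervals = []
    i = 0
    n = len(vals)
    while i < n:
        j = i
        while j < n and vals[j] == vals[i]:
            j += 1
        left = i == 0
        right = j == n
        censoring = ("both_censored" if left and right else
                     "left_censored" if left else
                     "right_censored" if right else "complete")
        intervals.append(StageInterval(
            k=int(vals[i]), start_frame=int(frames[i]),
            end_frame=int(frames[j - 1]),
            duration_s=float((j - i) * frame_interval_s),
            censoring=censoring))
        i = j
    series = pd.Series(vals, index=frames, name="dot_count")
    return DotStageSeries(counts=series, intervals=intervals,
                          frame_interval_s=frame_interval_s)


def intensity_ratio_report(
    intensities,
    labels=None,
    reference_label: str = "Aa1",
) -> dict:
    """Intensity ratios of the dots at one frame.

    Returns strongest/weakest and, when identities are available, each
    dot's ratio to the reference-class dot (an Aa1-type autosomal
    half-bivalent dot by convention).
    """
    vals = np.asarray(intensities, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two dots")
    if np.any(vals <= 0):
        raise ValueError("zero or negative dot intensity")
    report = {
        "strongest_over_weakest": float(vals.max() / vals.min()),
        "n_dots": int(vals.size),
    }
    if labels is not None:
        labels = list(labels)
        if reference_label in labels:
            ref = vals[labels.index(reference_label)]
            report["per_dot_over_reference"] = {
                lab: float(v / ref) for lab, v in zip(labels, vals)}
            report["reference_label"] = reference_label
    return report


def pair_separation(track_a, track_b, frames=None) -> pd.Series:
    """Per-frame Euclidean distance (um) between two tracked signals.

    Frames where exactly one of the two signals was detected encode 0
    (single-spot convention); frames where neither is present are missing
    values (NaN), never zero.
    """
    if frames is None:
        frames = sorted(set(track_a.frames) | set(track_b.frames))
    out = {}
    for f in frames:
        pa = track_a.position_at(f)
        pb = track_b.position_at(f)
        if pa is None and pb is None:
            out[f] = np.nan
        elif pa is None or pb is None:
            out[f] = 0.0
        else:
            out[f] = float(np.linalg.norm(pa - pb))
    return pd.Series(out, name="separation_um")


def separation_series(spots_by_frame: dict) -> pd.Series:
    """Separation of the two brightest spots per frame, from raw detections.

    One detected spot encodes 0; no spot is a missing value.  This mirrors
    the satellite-dot stretching readout where the splitting of a single
    dot is observed through the appearance of a second detection.
    """
    out = {}
    for f in sorted(spots_by_frame):
        spots = sorted(spots_by_frame[f],
                       key=lambda s: -s.integrated_intensity)
        if len(spots) == 0:
            out[f] = np.nan
        elif len(spots) == 1:
            out[f] = 0.0
        else:
            a, b = spots[0], spots[1]
            out[f] = float(np.linalg.norm(a.position_um - b.position_um))
    return pd.Series(out, name="separation_um")


def stretch_episodes(
    series: pd.Series,
    min_separation_um: float = 1.0,
    min_duration_frames: int = 3,
) -> list[StretchEpisode]:
    """Extract stretch episodes from a pair-separation series.

    An episode is a maximal run of frames with separation >=
    ``min_separation_um`` lasting at least ``min_duration_frames``.  Its
    outcome is ``definitive_split`` if the separation never returns to 0
    before the end of the observation, else ``relaxed``.
    """
    frames = series.index.to_numpy()
    vals = series.to_numpy(dtype=float)
    episodes = []
    i = 0
    n = len(vals)
    while i < n:
        if not np.isfinite(vals[i]) or vals[i] < min_separation_um:
            i += 1
            continue
        j = i
        while j < n and np.isfinite(vals[j]) and vals[j] >= min_separation_um:
            j += 1
        if j - i >= min_duration_frames:
            after = vals[j:]
            returns_to_zero = bool(np.any(after[np.isfinite(after)] == 0.0))
            episodes.append(StretchEpisode(
                start_frame=int(frames[i]), end_frame=int(frames[j - 1]),
                max_separation_um=float(np.nanmax(vals[i:j])),
                outcome="relaxed" if returns_to_zero else "definitive_split"))
        i = j
    return episodes


def radial_summary(track, nuclei, n_frames: int = 10) -> dict:
    """Mean +/- SD radial position of a track over the first frames of imaging.

    ``nuclei`` maps frame -> NucleusModel (or any object with
    ``centroid_um`` and ``radius_um``).  The radial position of each
    available frame among the first ``n_frames`` is
    (r_dot - 0) / R measured from the nucleus centroid, clipped to [0, 1].
    """
    vals = []
    for f in range(n_frames):
        pos = track.position_at(f)
        if pos is None or f not in nuclei:
            continue
        nuc = nuclei[f]
        r = float(np.linalg.norm(np.asarray(pos) - np.asarray(nuc.centroid_um)))
        vals.append(min(r / nuc.radius_um, 1.0))
    if not vals:
        warnings.warn("track has no frames within the radial summary window")
        return {"mean": np.nan, "sd": np.nan, "n": 0}
    arr = np.asarray(vals)
    return {"mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "n": int(arr.size)}


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(a, b, welch: bool = False) -> dict:
    """Two-sample two-tailed t test (classical Student by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            raise ValueError("zero variance in both groups")
        raise ValueError("zero variance in both groups")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {"t": float(t), "p": float(p), "stars": significance_stars(float(p)),
            "n_a": int(a.size), "n_b": int(b.size),
            "mean_a": float(a.mean()), "mean_b": float(b.mean())}
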