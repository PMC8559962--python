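"""Ground-truthed synthetic two-channel 4D movies of spermatocyte nuclei.

The generator emulates spinning-disc acquisitions of a single spermatocyte
nucleus: channel 0 carries a diffuse nuclear signal (His2Av-mRFP analog, a
soft-edged sphere with weak interior), channel 1 carries punctate markers
(centromere / telomere / satellite dots) rendered as anisotropic-Gaussian
PSF blobs whose integrated intensities follow the karyotype model.  Dots
move by anchored confined diffusion calibrated to a mean speed; the whole
scene can drift; Poisson + Gaussian noise and exponential photobleaching
are applied last.  A :class:`GroundTruth` records every true trajectory,
intensity, realized event and drift vector, so every downstream estimator
(detector, tracker, metrics, classifier) can be validated against it.

Event grammar: the wild-type centromere de-clustering program is a fixed
order of cluster splits taking the dot count 1 -> 8; two observed variants
reorder the first release from the most intense XY4 cluster.  Condensin II
mutant movies suppress splits and instead show stretch episodes (a dot
transiently elongates, usually to ~2 um, then relaxes); anaphase movies
move chromosomal entities to two poles, optionally with each univalent
choosing its pole by an independent fair coin (the random-segregation null).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Movie
from .karyotype import KaryotypeSpec, PairingConfig, male_karyotype, BIVALENTS

__all__ = [
    "AcquisitionConfig", "MotionConfig", "Event", "EventSchedule",
    "GroundTruth", "acquisition_m1", "acquisition_territory",
    "simulate_decluster_schedule", "simulate_stretch_schedule",
    "simulate_movie", "simulate_anaphase", "render_spots", "peak_amplitude",
    "background_noise_sd", "configure_snr", "DECLUSTER_PROGRAMS",
]

# mean of |N(0, I_3)|: sqrt(2) * Gamma(2) / Gamma(3/2)
_MEAN_CHI3 = float(np.sqrt(2.0) / (np.sqrt(np.pi) / 2.0))


@dataclass
class AcquisitionConfig:
    """Imaging geometry, optics and noise of one acquisition."""

    n_frames: int = 40
    frame_interval_s: float = 60.0
    z_planes: int = 29
    z_spacing_um: float = 0.8
    xy_pixel_um: float = 0.25
    ny: int = 96
    nx: int = 96
    # apparent size of a rendered dot (object size convolved with the PSF):
    # lateral FWHM ~0.47 um matches the ~500 nm dot class; axial ~3x wider
    psf_sigma_um: tuple = (0.6, 0.2, 0.2)     # (z, y, x)
    gaussian_sd: float = 2.0
    poisson_scale: float = 1.0                # 0 disables Poisson noise
    bleach_rate: float = 0.002                # fraction lost per frame
    photons_per_unit: float = 500.0           # integrated counts per intensity unit
    baseline: float = 10.0
    nuclear_amplitude: float = 40.0
    nuclear_edge_um: float = 0.4
    dot_channel_diffuse: float = 3.0          # weak nucleoplasmic signal in ch 1

    def __post_init__(self):
        if min(self.z_spacing_um, self.xy_pixel_um) <= 0:
            raise ValueError("voxel spacings must be > 0")
        if min(self.psf_sigma_um) <= 0:
            raise ValueError("psf_sigma must be > 0")

    @property
    def spacing(self):
        return (self.z_spacing_um, self.xy_pixel_um, self.xy_pixel_um)

    @property
    def shape(self):
        return (self.z_planes, self.ny, self.nx)

    @property
    def noise_off(self):
        return self.gaussian_sd == 0 and self.poisson_scale == 0


def acquisition_m1(**kw) -> AcquisitionConfig:
    """Meiosis-I geometry: 46 focal planes spaced by 500 nm, 45 s intervals."""
    defaults = dict(z_planes=46, z_spacing_um=0.5, frame_interval_s=45.0)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


def acquisition_territory(**kw) -> AcquisitionConfig:
    """Territory-formation geometry: 29 focal planes spaced by 800 nm."""
    defaults = dict(z_planes=29, z_spacing_um=0.8, frame_interval_s=600.0)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


@dataclass
class MotionConfig:
    """Dot motion, confinement and whole-scene drift.

    ``mean_speed_um_s`` calibrates the random step size so that the mean
    per-interval displacement equals speed x interval; anchored reversion
    plus a hard radius implement confined diffusion.  An optional two-state
    switch produces transient phases of faster movement.
    """

    mean_speed_um_s: float = 0.03
    confinement_radius_um: float = 0.5
    reversion: float = 0.1                 # pull-back toward the anchor per frame
    drift_um_per_frame: tuple = (0.0, 0.0, 0.0)
    fast_speed_um_s: float | None = None
    fast_switch_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_speed_um_s < 0:
            raise ValueError("mean_speed must be >= 0")


@dataclass
class Event:
    time_s: float
    kind: str               # split | fusion | stretch_start | stretch_end | anaphase
    parent: str
    children: tuple = ()
    partition_fraction: float | None = None
    magnitude_um: float | None = None   # stretch amplitude

    def __post_init__(self):
        if self.kind == "split" and self.partition_fraction is not None:
            if not 0.0 < self.partition_fraction < 1.0:
                raise ValueError("partition_fraction must be in (0, 1)")


@dataclass
class EventSchedule:
    events: list
    initial_dots: dict          # label -> intensity units at t = 0
    dot_intensities: dict       # label -> intensity units

    def __post_init__(self):
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")


@dataclass
class GroundTruth:
    """Simulator truth: trajectories, intensities, events, drift, nucleus."""

    dots: pd.DataFrame       # frame, time_s, dot_id, z/y/x_um (nucleus frame), intensity_units, elongation_um
    events: pd.DataFrame     # frame, time_s, kind, parent, child1, child2, partition_fraction, magnitude_um
    drift: pd.DataFrame      # frame, dz/dy/dx_um
    nucleus: pd.DataFrame    # frame, cz/cy/cx_um (image frame), radius_um
    pole_assignment: dict | None = None

    def dot_count_series(self) -> pd.Series:
        """True number of distinct dots per frame (stretch counts as one)."""
        return self.dots.groupby("frame")["dot_id"].nunique()

    def positions_at(self, frame: int) -> pd.DataFrame:
        return self.dots[self.dots["frame"] == frame]


# ---------------------------------------------------------------------------
# de-clustering schedules

DECLUSTER_PROGRAMS = ("canonical", "variant_four_dot", "variant_three_dot")

# split definitions: parent -> (child_small, child_large) with G2 unit
# intensities; 'rel1'/'rel2' are relabelled 'chr4'/'Y' (order seeded) because
# the two ~2-unit releases from XY4 are not distinguishable by intensity.
_G2_INTENSITY = {
    "all": 18.0, "Aa": 4.0, "Ab+XY4": 14.0, "Ab": 4.0, "XY4": 10.0,
    "Aa1": 2.0, "Aa2": 2.0, "Ab1": 2.0, "Ab2": 2.0,
    "XY4r": 6.0, "X": 2.0, "chr4": 4.0, "Y": 4.0, "4a": 2.0, "4b": 2.0,
}

_SPLITS = {
    "release_Aa": ("all", ("Aa", "Ab+XY4")),
    "release_Ab": ("Ab+XY4", ("Ab", "XY4")),
    "split_Aa": ("Aa", ("Aa1", "Aa2")),
    "split_Ab": ("Ab", ("Ab1", "Ab2")),
    "release_xy_1": ("XY4", ("REL1", "XY4r")),
    "release_xy_2": ("XY4r", ("REL2", "X")),
    "split_chr4": ("chr4", ("4a", "4b")),
}

_PROGRAM_ORDER = {
    # dot count goes 1..8; the XY4 releases move earlier in the variants
    "canonical": ["release_Aa", "release_Ab", "split_Aa", "split_Ab",
                  "release_xy_1", "release_xy_2", "split_chr4"],
    "variant_four_dot": ["release_Aa", "release_Ab", "split_Aa",
                         "release_xy_1", "split_Ab", "release_xy_2",
                         "split_chr4"],
    "variant_three_dot": ["release_Aa", "release_Ab", "release_xy_1",
                          "split_Aa", "split_Ab", "release_xy_2",
                          "split_chr4"],
}


def simulate_decluster_schedule(
    program: str,
    stage_durations,
    seed: int = 0,
) -> EventSchedule:
    """Build the split schedule of a wild-type de-clustering program.

    ``stage_durations`` gives the duration (seconds) of the k-dot stages for
    k = 1..7 (sequence, or mapping k -> seconds); the split taking the count
    from k to k+1 dots occurs at the cumulative end of the k-dot stage.  The
    seed only decides which of the two mid-weight XY4 releases is the chr4
    bivalent (which later splits) and which the Y sister pair.
    """
    if program not in DECLUSTER_PROGRAMS:
        raise ValueError(f"unknown program {program!r}; "
                         f"expected one of {DECLUSTER_PROGRAMS}")
    if isinstance(stage_durations, dict):
        durations = [float(stage_durations[k]) for k in range(1, 8)]
    else:
        durations = [float(d) for d in stage_durations]
    if len(durations) != 7:
        raise ValueError("need durations for the 1..7-dot stages")
    if any(d < 0 for d in durations):
        raise ValueError("durations must be non-negative")

    rng = np.random.default_rng(seed)
    rel_labels = ["chr4", "Y"]
    if rng.random() < 0.5:
        rel_labels.reverse()
    relabel = {"REL1": rel_labels[0], "REL2": rel_labels[1]}

    events = []
    t = 0.0
    for stage_k, split_name in enumerate(_PROGRAM_ORDER[program], start=1):
        t += durations[stage_k - 1]
        parent, (c1, c2) = _SPLITS[split_name]
        c1, c2 = relabel.get(c1, c1), relabel.get(c2, c2)
        parent = relabel.get(parent, parent)
        i1, i2 = _G2_INTENSITY[c1], _G2_INTENSITY[c2]
        events.append(Event(time_s=t, kind="split", parent=parent,
                            children=(c1, c2),
                            partition_fraction=i1 / (i1 + i2)))
    return EventSchedule(events=events, initial_dots={"all": _G2_INTENSITY["all"]},
                         dot_intensities=dict(_G2_INTENSITY))


def simulate_stretch_schedule(
    episodes,
    dot_label: str = "G",
    intensity: float = 4.0,
    definitive_split_time_s: float | None = None,
) -> EventSchedule:
    """Schedule stretch episodes of a single satellite dot.

    ``episodes`` is a list of (start_s, end_s, max_separation_um).  With
    ``definitive_split_time_s`` the dot splits for good at that time
    (children inherit half the intensity each).
    """
    events = []
    for start, end, amp in episodes:
        if end < start or amp <= 0:
            raise ValueError("episode needs end >= start and amplitude > 0")
        events.append(Event(start, "stretch_start", dot_label, magnitude_um=amp))
        events.append(Event(end, "stretch_end", dot_label))
    intensities = {dot_label: intensity}
    if definitive_split_time_s is not None:
        ca, cb = f"{dot_label}a", f"{dot_label}b"
        events.append(Event(definitive_split_time_s, "split", dot_label,
                            children=(ca, cb), partition_fraction=0.5))
        intensities[ca] = intensities[cb] = intensity / 2.0
    events.sort(key=lambda e: e.time_s)
    return EventSchedule(events=events, initial_dots={dot_label: intensity},
                         dot_intensities=intensities)


# ---------------------------------------------------------------------------
# rendering


def background_noise_sd(acq: AcquisitionConfig) -> float:
    """SD of the combined Poisson + Gaussian noise on background voxels."""
    poisson_var = acq.baseline / acq.poisson_scale if acq.poisson_scale > 0 else 0.0
    return float(np.sqrt(acq.gaussian_sd ** 2 + poisson_var))


def configure_snr(acq: AcquisitionConfig, snr: float,
                  min_intensity_units: float = 2.0) -> AcquisitionConfig:
    """Rescale photons so the dimmest dot has the requested signal-to-noise.

    SNR is peak signal over the total noise SD at the peak (Gaussian read
    noise plus shot noise of baseline + signal), the usual working
    definition for fluorescent spots.  Solving
    ``p = snr * sqrt(g^2 + (b + p)/c)`` for the peak ``p``:
    """
    g, b, c = acq.gaussian_sd, acq.baseline, acq.poisson_scale
    if g == 0 and c == 0:
        return acq
    s2 = snr ** 2
    if c > 0:
        target_peak = (s2 / c + np.sqrt((s2 / c) ** 2
                                        + 4.0 * s2 * (g ** 2 + b / c))) / 2.0
    else:
        target_peak = snr * g
    scale = target_peak / peak_amplitude(min_intensity_units, acq)
    return replace(acq, photons_per_unit=acq.photons_per_unit * scale)


def peak_amplitude(intensity_units: float, acq: AcquisitionConfig) -> float:
    """Peak voxel value of a dot with the given integrated intensity units."""
    sz, sy, sx = acq.psf_sigma_um
    total = intensity_units * acq.photons_per_unit
    voxvol = acq.z_spacing_um * acq.xy_pixel_um ** 2
    return total * voxvol / ((2.0 * np.pi) ** 1.5 * sz * sy * sx)


def render_spots(shape, spacing, positions_um, intensities, psf_sigma_um,
                 photons_per_unit=1.0, out=None):
    """Render PSF-blurred Gaussian spots onto a voxel grid.

    The voxel sum of each rendered spot equals
    ``intensity * photons_per_unit`` (up to < 1% truncation at 4 sigma).
    Voxel centres sit at ``index * spacing``.
    """
    vol = out if out is not None else np.zeros(shape, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    sig = np.asarray(psf_sigma_um, dtype=float)
    voxvol = float(np.prod(spacing))
    norm = voxvol / ((2.0 * np.pi) ** 1.5 * np.prod(sig))
    half = np.ceil(4.0 * sig / spacing).astype(int)
    for pos, inten in zip(positions_um, intensities):
        pos = np.asarray(pos, dtype=float)
        ctr = pos / spacing
        lo = np.maximum(np.floor(ctr).astype(int) - half, 0)
        hi = np.minimum(np.floor(ctr).astype(int) + half + 1, shape)
        if np.any(lo >= hi):
            continue
        axes = [np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
        g = [np.exp(-0.5 * ((ax - pos[a]) / sig[a]) ** 2)
             for a, ax in enumerate(axes)]
        blob = g[0][:, None, None] * g[1][None, :, None] * g[2][None, None, :]
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
            inten * photons_per_unit * norm * blob
    return vol


def _render_nucleus(shape, spacing, center_um, radius_um, amplitude, edge_um):
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    zz = (axes[0] - center_um[0])[:, None, None]
    yy = (axes[1] - center_um[1])[None, :, None]
    xx = (axes[2] - center_um[2])[None, None, :]
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    return amplitude / (1.0 + np.exp((r - radius_um) / edge_um))


# ---------------------------------------------------------------------------
# movie simulation


class _Dot:
    __slots__ = ("label", "pos", "anchor", "prev_disp", "intensity",
                 "stretch_amp", "stretch_axis", "stretch_t0", "stretch_t1")

    def __init__(self, label, pos, intensity):
        self.label = label
        self.pos = np.asarray(pos, dtype=float)
        self.anchor = self.pos.copy()
        self.prev_disp = np.zeros(3)
        self.intensity = float(intensity)
        self.stretch_amp = None
        self.stretch_axis = None
        self.stretch_t0 = self.stretch_t1 = 0.0


def _unit_vector(rng):
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _step(dot: _Dot, motion: MotionConfig, dt: float, rng) -> None:
    speed = motion.mean_speed_um_s
    if motion.fast_speed_um_s and rng.random() < motion.fast_switch_prob:
        speed = motion.fast_speed_um_s
    sd = speed * dt / _MEAN_CHI3
    disp = motion.reversion * (dot.anchor - dot.pos)
    if sd > 0:
        disp = disp + rng.normal(scale=sd, size=3)
    new = dot.pos + disp
    off = new - dot.anchor
    r = np.linalg.norm(off)
    if r > motion.confinement_radius_um > 0:
        new = dot.anchor + off * (motion.confinement_radius_um / r)
    dot.prev_disp = new - dot.pos
    dot.pos = new


def _elongation(dot: _Dot, t: float) -> float:
    """Triangular stretch profile: 0 -> amplitude -> 0 across the episode."""
    if dot.stretch_amp is None or not dot.stretch_t0 <= t <= dot.stretch_t1:
        return 0.0
    span = dot.stretch_t1 - dot.stretch_t0
    if span <= 0:
        return dot.stretch_amp
    u = (t - dot.stretch_t0) / span
    return dot.stretch_amp * (1.0 - abs(2.0 * u - 1.0))


def simulate_movie(
    karyotype: KaryotypeSpec | None = None,
    schedule: EventSchedule | None = None,
    motion: MotionConfig | None = None,
    acq: AcquisitionConfig | None = None,
    mode: str = "wildtype",
    nucleus_radius_um: float = 4.0,
    child_spawn_separation_um: float = 1.0,
    anchor_separation_um: float = 2.0,
    territory_repulsion_um: float = 1.4,
    stretch_max_um: float = 2.0,
    stretch_duration_s: float | None = None,
    rare_split_prob: float = 0.0,
) -> tuple[Movie, GroundTruth]:
    """Simulate a two-channel movie and its ground truth.

    ``mode='wildtype'`` realizes the schedule's splits as given.
    ``mode='condensinII_mutant'`` suppresses split events and replaces each
    by a stretch episode (amplitude ``stretch_max_um``, default duration
    10 frames), with an optional rare definitive split
    (``rare_split_prob`` per suppressed split).
    ``mode='overexpression'`` ignores the schedule and renders four resolved
    satellite dots from frame 0.
    """
    karyotype = karyotype or male_karyotype("G2")
    motion = motion or MotionConfig()
    acq = acq or acquisition_territory()
    if mode not in ("wildtype", "condensinII_mutant", "overexpression"):
        raise ValueError(f"unknown mode {mode!r}")

    root = np.random.default_rng(motion.seed)
    rng_schedule, rng_motion, rng_noise = root.spawn(3)

    duration = acq.n_frames * acq.frame_interval_s
    if schedule is not None:
        late = [e for e in schedule.events if e.time_s > duration]
        if late:
            raise ValueError(
                f"{len(late)} scheduled events fall after the movie ends "
                f"({duration} s)")

    if mode == "overexpression":
        schedule = EventSchedule(
            events=[], initial_dots={f"sat{i}": 1.0 for i in range(4)},
            dot_intensities={f"sat{i}": 1.0 for i in range(4)})
    elif schedule is None:
        raise ValueError("a schedule is required outside overexpression mode")

    events = list(schedule.events)
    if mode == "condensinII_mutant":
        # suppress splits: each split of a dot that actually exists becomes
        # a stretch episode of that dot (or, rarely, a definitive split);
        # splits of products that consequently never form are dropped
        dur = stretch_duration_s or 10.0 * acq.frame_interval_s
        alive = set(schedule.initial_dots)
        replaced = []
        for e in events:
            if e.kind != "split":
                replaced.append(e)
                continue
            if e.parent not in alive:
                continue
            if rare_split_prob > 0 and rng_schedule.random() < rare_split_prob:
                replaced.append(e)  # rare definitive split
                alive.discard(e.parent)
                alive.update(e.children)
                continue
            t1 = min(e.time_s + dur, duration - acq.frame_interval_s)
            replaced.append(Event(e.time_s, "stretch_start", e.parent,
                                  magnitude_um=stretch_max_um))
            replaced.append(Event(t1, "stretch_end", e.parent))
        replaced.sort(key=lambda e: e.time_s)
        events = replaced

    spacing = np.asarray(acq.spacing, dtype=float)
    extent = np.asarray(acq.shape) * spacing
    center0 = extent / 2.0
    R = nucleus_radius_um
    if R >= min(extent) / 2.0:
        raise ValueError("nucleus does not fit in the field of view")

    # initial dots inside the nucleus (within 0.6 R of the centre)
    dots: dict[str, _Dot] = {}
    for label, inten in schedule.initial_dots.items():
        pos = center0 * 0 + _unit_vector(rng_motion) * (0.6 * R * rng_motion.random())
        dots[label] = _Dot(label, pos, inten)  # nucleus frame (0 = centroid)
    for d in dots.values():
        if np.linalg.norm(d.pos) >= R:
            raise ValueError(f"dot {d.label} initialized outside the nucleus")

    drift_vec = np.asarray(motion.drift_um_per_frame, dtype=float)
    dt = acq.frame_interval_s

    truth_rows, event_rows, drift_rows, nuc_rows = [], [], [], []
    movie = np.zeros((acq.n_frames, 2) + acq.shape, dtype=np.float32)
    pending = sorted(events, key=lambda e: e.time_s)
    realized_i = 0

    for f in range(acq.n_frames):
        t = f * dt
        # realize events scheduled up to this frame time
        while realized_i < len(pending) and pending[realized_i].time_s <= t:
            e = pending[realized_i]
            realized_i += 1
            if e.kind == "split":
                parent = dots.pop(e.parent)
                u = _unit_vector(rng_motion)
                pf = e.partition_fraction if e.partition_fraction is not None else 0.5
                # if the split terminates a stretch, children appear at the
                # stretch endpoints
                el = _elongation(parent, t)
                sep = max(child_spawn_separation_um, el)
                for sign, lab, frac in ((1.0, e.children[0], pf),
                                        (-1.0, e.children[1], 1.0 - pf)):
                    axis = parent.stretch_axis if el > 0 else u
                    child = _Dot(lab, parent.pos + sign * axis * sep / 2.0,
                                 parent.intensity * frac)
                    anchor = parent.anchor + sign * axis * anchor_separation_um / 2.0
                    r = np.linalg.norm(anchor)
                    if r > 0.75 * R:  # anchors stay inside the nucleus
                        anchor *= 0.75 * R / r
                    child.anchor = anchor
                    dots[lab] = child
                event_rows.append(dict(frame=f, time_s=e.time_s, kind="split",
                                       parent=e.parent, child1=e.children[0],
                                       child2=e.children[1],
                                       partition_fraction=pf,
                                       magnitude_um=np.nan))
            elif e.kind == "fusion":
                c1, c2 = (dots.pop(c) for c in e.children)
                merged = _Dot(e.parent, (c1.pos + c2.pos) / 2.0,
                              c1.intensity + c2.intensity)
                dots[e.parent] = merged
                event_rows.append(dict(frame=f, time_s=e.time_s, kind="fusion",
                                       parent=e.parent, child1=e.children[0],
                                       child2=e.children[1],
                                       partition_fraction=np.nan,
                                       magnitude_um=np.nan))
            elif e.kind == "stretch_start":
                d = dots[e.parent]
                d.stretch_amp = e.magnitude_um or stretch_max_um
                d.stretch_axis = _unit_vector(rng_motion)
                d.stretch_t0 = e.time_s
                # find matching end
                d.stretch_t1 = next(
                    (x.time_s for x in pending[realized_i:]
                     if x.kind == "stretch_end" and x.parent == e.parent),
                    duration)
                event_rows.append(dict(frame=f, time_s=e.time_s,
                                       kind="stretch_start", parent=e.parent,
                                       child1="", child2="",
                                       partition_fraction=np.nan,
                                       magnitude_um=d.stretch_amp))
            elif e.kind == "stretch_end":
                event_rows.append(dict(frame=f, time_s=e.time_s,
                                       kind="stretch_end", parent=e.parent,
                                       child1="", child2="",
                                       partition_fraction=np.nan,
                                       magnitude_um=np.nan))

        # motion; anchors repel like separating territories so distinct
        # clusters occupy distinct subnuclear regions
        if f > 0:
            labels_sorted = sorted(dots)
            for i, la in enumerate(labels_sorted):
                for lb in labels_sorted[i + 1:]:
                    a, b = dots[la], dots[lb]
                    v = a.anchor - b.anchor
                    dist = np.linalg.norm(v)
                    if 0 < dist < territory_repulsion_um:
                        push = v / dist * 0.08
                        for dot, sgn in ((a, 1.0), (b, -1.0)):
                            na = dot.anchor + sgn * push
                            r = np.linalg.norm(na)
                            if r > 0.75 * R:
                                na *= 0.75 * R / r
                            dot.anchor = na
            for d in dots.values():
                _step(d, motion, dt, rng_motion)

        drift = drift_vec * f
        center = center0 + drift
        bleach = (1.0 - acq.bleach_rate) ** f

        # truth
        for d in dots.values():
            el = _elongation(d, t)
            truth_rows.append(dict(frame=f, time_s=t, dot_id=d.label,
                                   z_um=d.pos[0], y_um=d.pos[1], x_um=d.pos[2],
                                   intensity_units=d.intensity,
                                   elongation_um=el))
        drift_rows.append(dict(frame=f, dz_um=drift[0], dy_um=drift[1],
                               dx_um=drift[2]))
        nuc_rows.append(dict(frame=f, cz_um=center[0], cy_um=center[1],
                             cx_um=center[2], radius_um=R))

        # render channel 0 (diffuse nuclear)
        movie[f, 0] = acq.baseline + bleach * _render_nucleus(
            acq.shape, spacing, center, R, acq.nuclear_amplitude,
            acq.nuclear_edge_um)
        # render channel 1 (dots + weak diffuse)
        ch1 = np.full(acq.shape, float(acq.baseline))
        if acq.dot_channel_diffuse > 0:
            ch1 += bleach * _render_nucleus(acq.shape, spacing, center, R,
                                            acq.dot_channel_diffuse,
                                            acq.nuclear_edge_um)
        positions, intensities = [], []
        for d in dots.values():
            el = _elongation(d, t)
            if el > 0:
                for sign in (1.0, -1.0):
                    positions.append(center + d.pos + sign * d.stretch_axis * el / 2.0)
                    intensities.append(d.intensity / 2.0 * bleach)
            else:
                positions.append(center + d.pos)
                intensities.append(d.intensity * bleach)
        render_spots(acq.shape, spacing, positions, intensities,
                     acq.psf_sigma_um, acq.photons_per_unit, out=ch1)
        movie[f, 1] = ch1

    # noise (one pass; substream independent of motion)
    if acq.poisson_scale > 0:
        movie = rng_noise.poisson(
            np.clip(movie, 0, None) * acq.poisson_scale
        ).astype(np.float32) / acq.poisson_scale
    if acq.gaussian_sd > 0:
        movie = movie + rng_noise.normal(
            0.0, acq.gaussian_sd, size=movie.shape).astype(np.float32)

    gt = GroundTruth(
        dots=pd.DataFrame(truth_rows),
        events=pd.DataFrame(event_rows, columns=["frame", "time_s", "kind",
                                                 "parent", "child1", "child2",
                                                 "partition_fraction",
                                                 "magnitude_um"]),
        drift=pd.DataFrame(drift_rows),
        nucleus=pd.DataFrame(nuc_rows),
    )
    return Movie(movie, tuple(spacing), acq.frame_interval_s), gt


# ---------------------------------------------------------------------------
# anaphase


def simulate_anaphase(
    karyotype: KaryotypeSpec | None = None,
    pairing: PairingConfig | None = None,
    null_random: bool = False,
    seed: int = 0,
    acq: AcquisitionConfig | None = None,
    pole_distance_um: float = 3.0,
    render: bool = True,
) -> tuple[Movie | None, GroundTruth]:
    """Simulate anaphase I segregation of chromosomal entities to two poles.

    Intact bivalents always send their two univalents to opposite poles
    (4:4 by construction when all are intact).  With ``null_random`` each
    univalent of a disrupted bivalent picks its pole by an independent fair
    coin; otherwise disrupted univalents also segregate properly.  The truth
    records the pole of every univalent (one centromere unit per chromosome).
    """
    karyotype = (karyotype or male_karyotype("G2")).with_phase("G2")
    pairing = pairing or PairingConfig()
    acq = acq or acquisition_m1(n_frames=10, ny=64, nx=64, z_planes=24)
    rng = np.random.default_rng(seed)

    members = {"chr2": ("chr2.0", "chr2.1"), "chr3": ("chr3.0", "chr3.1"),
               "chr4": ("chr4.0", "chr4.1"), "XY": ("chrX", "chrY")}
    weights = {}
    k = karyotype.chromatids_per_chromosome
    for biv, (u1, u2) in members.items():
        for unit in (u1, u2):
            name = unit.split(".")[0]
            weights[unit] = karyotype.chromosome(name).centromere_unit_intensity * k

    pole_of: dict[str, int] = {}
    for biv in BIVALENTS:
        u1, u2 = members[biv]
        if pairing.conjunction_intact[biv] or not null_random:
            first = int(rng.integers(2))
            pole_of[u1], pole_of[u2] = first, 1 - first
        else:
            pole_of[u1] = int(rng.integers(2))
            pole_of[u2] = int(rng.integers(2))

    spacing = np.asarray(acq.spacing, dtype=float)
    extent = np.asarray(acq.shape) * spacing
    center = extent / 2.0
    axis = np.array([0.0, 0.0, 1.0])  # poles along x

    truth_rows, nuc_rows, drift_rows = [], [], []
    n_frames = acq.n_frames
    movie = np.zeros((n_frames, 2) + acq.shape, dtype=np.float32) if render else None
    start = {u: rng.normal(scale=0.4, size=3) for u in pole_of}
    for f in range(n_frames):
        frac = f / max(n_frames - 1, 1)
        positions, intensities = [], []
        for u, pole in pole_of.items():
            target = axis * pole_distance_um * (1 if pole == 0 else -1)
            pos = start[u] * (1 - frac) + target * frac
            truth_rows.append(dict(frame=f, time_s=f * acq.frame_interval_s,
                                   dot_id=u, z_um=pos[0], y_um=pos[1],
                                   x_um=pos[2], intensity_units=weights[u],
                                   elongation_um=0.0))
            positions.append(center + pos)
            intensities.append(weights[u])
        nuc_rows.append(dict(frame=f, cz_um=center[0], cy_um=center[1],
                             cx_um=center[2], radius_um=pole_distance_um + 1.0))
        drift_rows.append(dict(frame=f, dz_um=0.0, dy_um=0.0, dx_um=0.0))
        if render:
            vol = np.full(acq.shape, float(acq.baseline))
            render_spots(acq.shape, spacing, positions, intensities,
                         acq.psf_sigma_um, acq.photons_per_unit, out=vol)
            movie[f, 1] = vol
            movie[f, 0] = acq.baseline

    if render and not acq.noise_off:
        rng_noise = np.random.default_rng(seed + 1)
        if acq.poisson_scale > 0:
            movie = rng_noise.poisson(
                np.clip(movie, 0, None) * acq.poisson_scale
            ).astype(np.float32) / acq.poisson_scale
        if acq.gaussian_sd > 0:
            movie = movie + rng_noise.normal(
                0.0, acq.gaussian_sd, movie.shape).astype(np.float32)

    gt = GroundTruth(
        dots=pd.DataFrame(truth_rows),
        events=pd.DataFrame(columns=["frame", "time_s", "kind", "parent",
                                     "child1", "child2", "partition_fraction",
                                     "magnitude_um"]),
        drift=pd.DataFrame(drift_rows),
        nucleus=pd.DataFrame(nuc_rows),
        pole_assignment=pole_of,
    )
    out_movie = Movie(movie, tuple(spacing), acq.frame_interval_s) if render else None
    return out_movie, gt
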