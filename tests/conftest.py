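import numpy as np
import pytest

from chromotrace.detect import detect_spots
from chromotrace.nucleus import segment_nucleus
from chromotrace.simulate import (AcquisitionConfig, MotionConfig,
                                  simulate_decluster_schedule, simulate_movie)
from chromotrace.tracking import correct_drift, link_tracks


def small_acq(**kw):
    """Territory-style geometry scaled to test size (16 planes x 64 x 64)."""
    defaults = dict(n_frames=48, frame_interval_s=5.0, z_planes=16,
                    z_spacing_um=0.8, ny=64, nx=64, bleach_rate=0.0005)
    defaults.update(kw)
    return AcquisitionConfig(**defaults)


def run_decluster_pipeline(program, seed, acq=None, drift=(0.0, 0.01, 0.015)):
    """Simulate a de-clustering movie and run detect -> link -> drift-correct."""
    sched = simulate_decluster_schedule(program, [30.0] * 7, seed=seed)
    acq = acq or small_acq()
    motion = MotionConfig(seed=seed, drift_um_per_frame=drift)
    movie, gt = simulate_movie(schedule=sched, motion=motion, acq=acq,
                               nucleus_radius_um=3.5)
    spots, cents = [], {}
    for t in range(movie.n_frames):
        spots += detect_spots(movie.frame(t, 1), movie.spacing, 0.5,
                              frame_index=t)
        cents[t] = segment_nucleus(movie.frame(t, 0), movie.spacing).centroid_um
    tracks = link_tracks(spots, max_gap=2, max_step=0.6)
    tracks, drift_series = correct_drift(tracks, cents)
    # express corrected positions in the nucleus frame used by the truth
    c0 = gt.nucleus.iloc[0][["cz_um", "cy_um", "cx_um"]].to_numpy()
    for tr in tracks:
        tr.corrected_um = [p - c0 for p in tr.corrected_um]
    return movie, gt, tracks, drift_series


@pytest.fixture(scope="session")
def canonical_run():
    """One canonical-program pipeline run shared across tests."""
    return run_decluster_pipeline("canonical", seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
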