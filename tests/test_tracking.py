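"""Linking, drift correction, velocities, split/fusion calling, edits."""

import numpy as np
import pandas as pd
import pytest

from chromotrace.detect import SpotRecord
from chromotrace.tracking import (Track, apply_edits, compute_velocities,
                                  correct_drift, detect_splits_fusions,
                                  link_tracks, tracks_to_table,
                                  velocity_summary)


def spot(frame, pos, intensity=100.0):
    return SpotRecord(frame=frame, channel=1,
                      position_um=np.asarray(pos, dtype=float),
                      estimated_diameter_um=0.5,
                      integrated_intensity=intensity, quality=10.0)


def make_track(tid, frames, positions, intensities=None):
    tr = Track(track_id=tid)
    tr.frames = list(frames)
    tr.positions_um = [np.asarray(p, dtype=float) for p in positions]
    tr.intensities = list(intensities or [100.0] * len(tr.frames))
    tr.qualities = [1.0] * len(tr.frames)
    return tr


class TestLinking:
    def test_single_moving_dot_one_track(self):
        spots = [spot(f, [5.0, 5.0, 5.0 + 0.1 * f]) for f in range(20)]
        tracks = link_tracks(spots, max_step=0.5)
        assert len(tracks) == 1
        assert tracks[0].frames == list(range(20))

    def test_crossing_dots_keep_identity_with_motion_model(self):
        # two dots moving on straight opposite courses in y, passing at
        # x-separation > max_step of each other's constant-velocity
        # prediction
        spots = []
        for f in range(21):
            spots.append(spot(f, [5.0, 2.0 + 0.3 * f, 5.0], intensity=100))
            spots.append(spot(f, [5.0, 8.0 - 0.3 * f, 5.2], intensity=200))
        tracks = link_tracks(spots, max_step=0.45, motion_memory=1.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = [p[1] for p in tr.positions_um]
            steps = np.diff(ys)
            assert np.all(steps > 0) or np.all(steps < 0)  # no identity swap

    def test_empty_frames_terminate_tracks(self):
        spots = [spot(f, [5.0, 5.0, 5.0]) for f in (0, 1, 2, 6, 7)]
        tracks = link_tracks(spots, max_gap=1, max_step=0.5)
        assert sorted(len(t) for t in tracks) == [2, 3]

    def test_gap_closing(self):
        spots = [spot(f, [5.0, 5.0, 5.0]) for f in (0, 1, 3, 4)]
        tracks = link_tracks(spots, max_gap=2, max_step=0.5)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 3, 4]

    def test_permutation_invariance(self, rng):
        base = []
        for f in range(10):
            for k in range(4):
                base.append(spot(f, [5.0, 2.0 + 2 * k, 5.0 + 0.05 * f],
                                 intensity=50 * (k + 1)))
        t1 = link_tracks(list(base), max_step=0.5)
        shuffled = list(base)
        rng.shuffle(shuffled)
        t2 = link_tracks(shuffled, max_step=0.5)
        key = lambda trs: sorted(tuple(map(tuple, np.round(tr.positions(False), 6)))
                                 for tr in trs)
        assert key(t1) == key(t2)


class TestDrift:
    def test_linear_drift_removed(self):
        drift = np.array([0.0, 0.03, 0.05])
        tracks = [make_track(0, range(20),
                             [np.array([5.0, 5.0, 5.0]) + f * drift
                              for f in range(20)])]
        cents = {f: np.array([8.0, 8.0, 8.0]) + f * drift for f in range(20)}
        tracks, series = correct_drift(tracks, cents)
        pos = tracks[0].positions(corrected=True)
        assert np.abs(pos - pos[0]).max() < 0.1
        np.testing.assert_allclose(series.drift_um[0], 0.0)

    def test_zero_drift_leaves_positions_unchanged(self):
        tracks = [make_track(0, range(5), [[5.0, 5.0, 5.0 + 0.1 * f]
                                           for f in range(5)])]
        cents = {f: np.array([8.0, 8.0, 8.0]) for f in range(5)}
        tracks, _ = correct_drift(tracks, cents)
        np.testing.assert_allclose(tracks[0].positions(True),
                                   tracks[0].positions(False))

    def test_pairwise_distances_invariant(self):
        drift = np.array([0.01, 0.02, 0.0])
        t0 = make_track(0, range(10), [np.array([5.0, 4.0, 5.0]) + f * drift
                                       for f in range(10)])
        t1 = make_track(1, range(10), [np.array([5.0, 7.0, 5.5]) + f * drift
                                       for f in range(10)])
        before = [np.linalg.norm(a - b) for a, b in
                  zip(t0.positions(False), t1.positions(False))]
        (t0, t1), _ = correct_drift([t0, t1],
                                    {f: np.array([8.0, 8.0, 8.0]) + f * drift
                                     for f in range(10)})
        after = [np.linalg.norm(a - b) for a, b in
                 zip(t0.positions(True), t1.positions(True))]
        np.testing.assert_allclose(after, before, atol=1e-9)

    def test_missing_centroid_interpolated_with_warning(self):
        tracks = [make_track(0, range(5), [[5.0, 5.0, 5.0]] * 5)]
        cents = {0: np.zeros(3), 1: np.zeros(3), 3: np.zeros(3),
                 4: np.zeros(3)}
        with pytest.warns(UserWarning):
            correct_drift(tracks, cents)


class TestVelocities:
    def test_static_dot_zero_speed(self):
        tr = make_track(0, range(10), [[5.0, 5.0, 5.0]] * 10)
        assert np.all(compute_velocities(tr, 5.0) == 0.0)

    def test_interval_halved_doubles_speed(self):
        tr = make_track(0, range(10), [[5.0, 5.0, 5.0 + 0.1 * f]
                                       for f in range(10)])
        v1 = compute_velocities(tr, 10.0)
        v2 = compute_velocities(tr, 5.0)
        np.testing.assert_allclose(v2, 2 * v1)

    def test_length_one_track_empty_series(self):
        tr = make_track(0, [0], [[5.0, 5.0, 5.0]])
        assert compute_velocities(tr, 5.0).size == 0

    def test_summary_pools_tracks(self):
        t0 = make_track(0, range(5), [[5, 5, 5 + 0.1 * f] for f in range(5)])
        t1 = make_track(1, range(5), [[5, 5, 5 + 0.2 * f] for f in range(5)])
        mean, sd, n = velocity_summary([t0, t1], 1.0)
        assert n == 8
        assert mean == pytest.approx(0.15, rel=1e-6)


class TestSplitsFusions:
    def _split_scenario(self):
        # parent at intensity 300 drops to 200 when a 100-intensity child
        # appears nearby at frame 5
        parent = make_track(0, range(10),
                            [[5.0, 5.0, 5.0]] * 10,
                            [300.0] * 5 + [200.0] * 5)
        child = make_track(1, range(5, 10),
                           [[5.0, 5.0 + 0.2 * (f - 4), 5.0]
                            for f in range(5, 10)],
                           [100.0] * 5)
        return [parent, child]

    def test_split_called_with_partition_fraction(self):
        tracks = self._split_scenario()
        splits, fusions = detect_splits_fusions(tracks, window=2)
        assert len(splits) == 1
        ev = splits[0]
        assert ev.frame == 5 and ev.parent_id == 0 and ev.child1_id == 1
        assert ev.partition_fraction == pytest.approx(100 / 300, abs=0.05)
        assert tracks[1].parent_id == 0

    def test_no_events_without_intensity_change(self):
        t0 = make_track(0, range(10), [[5.0, 5.0, 5.0]] * 10)
        t1 = make_track(1, range(10), [[5.0, 8.0, 5.0]] * 10)
        splits, fusions = detect_splits_fusions([t0, t1])
        assert splits == [] and fusions == []

    def test_fusion_called_on_transient_merge(self):
        # two dots merge at frame 5: one track ends, the survivor's
        # intensity jumps by the vanished dot's amount
        a = make_track(0, range(5), [[5.0, 5.0, 5.0]] * 5, [100.0] * 5)
        b = make_track(1, range(10), [[5.0, 5.4, 5.0]] * 10,
                       [150.0] * 5 + [250.0] * 5)
        splits, fusions = detect_splits_fusions([a, b], window=2)
        assert len(fusions) == 1
        assert fusions[0].frame == 5 and fusions[0].track2_id == 1


class TestEdits:
    def test_add_delete_cut_join(self):
        tr = make_track(0, range(6), [[5.0, 5.0, 5.0 + 0.1 * f]
                                      for f in range(6)])
        tracks = [tr]
        edits = pd.DataFrame([
            {"op": "delete_spot", "track_id": 0, "frame": 2},
            {"op": "cut", "track_id": 0, "frame": 4},
        ])
        tracks = apply_edits(tracks, edits)
        assert sorted(tuple(t.frames) for t in tracks) == \
            [(0, 1, 3), (4, 5)]
        join = pd.DataFrame([{"op": "join", "track_id": 0, "frame": 0,
                              "other_track_id": tracks[1].track_id}])
        tracks = apply_edits(tracks, join)
        assert len(tracks) == 1 and tracks[0].frames == [0, 1, 3, 4, 5]

    def test_table_roundtrip_columns(self):
        tr = make_track(0, range(3), [[1.0, 2.0, 3.0]] * 3)
        df = tracks_to_table([tr])
        assert list(df.columns)[:2] == ["track_id", "frame"]
        assert len(df) == 3
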