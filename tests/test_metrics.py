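"""Stage intervals, intensity ratios, separations, stretching, group tests."""

import numpy as np
import pandas as pd
import pytest

from chromotrace.metrics import (compare_groups, dot_stage_intervals,
                                 intensity_ratio_report, pair_separation,
                                 significance_stars, stretch_episodes)
from chromotrace.tracking import Track


def make_track(tid, frames, positions):
    tr = Track(track_id=tid)
    tr.frames = list(frames)
    tr.positions_um = [np.asarray(p, dtype=float) for p in positions]
    tr.intensities = [1.0] * len(tr.frames)
    tr.qualities = [1.0] * len(tr.frames)
    return tr


class TestStageIntervals:
    def test_run_length_arithmetic(self):
        ds = dot_stage_intervals([3, 3, 4, 4, 4, 5], frame_interval_s=600)
        four = [iv for iv in ds.intervals if iv.k == 4][0]
        assert four.duration_s == 3 * 600
        assert four.censoring == "complete"

    def test_edge_runs_are_censored(self):
        ds = dot_stage_intervals([3, 3, 4, 4, 4, 5], frame_interval_s=600)
        assert ds.intervals[0].censoring == "left_censored"
        assert ds.intervals[-1].censoring == "right_censored"
        assert ds.intervals[0].is_minimal_duration

    def test_intervals_tile_observation_window(self):
        counts = [1, 2, 2, 3, 3, 3, 4, 4, 5, 5, 5, 5]
        ds = dot_stage_intervals(counts, frame_interval_s=60, debounce=0)
        assert sum(iv.duration_s for iv in ds.intervals) == len(counts) * 60

    def test_transient_fusion_bridged(self):
        counts = [4, 4, 4, 3, 4, 4, 5, 5]
        ds = dot_stage_intervals(counts, frame_interval_s=60, debounce=2)
        ks = [iv.k for iv in ds.intervals]
        assert 3 not in ks
        four = [iv for iv in ds.intervals if iv.k == 4][0]
        assert four.duration_s == 6 * 60

    def test_debounce_zero_keeps_dip(self):
        counts = [4, 4, 3, 4, 4]
        ds = dot_stage_intervals(counts, frame_interval_s=60, debounce=0)
        assert [iv.k for iv in ds.intervals] == [4, 3, 4]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            dot_stage_intervals([1, -1], frame_interval_s=60)


class TestIntensityRatios:
    def test_expected_four_dot_ratio(self):
        rep = intensity_ratio_report([6.0, 4.0, 4.0, 4.0])
        assert rep["strongest_over_weakest"] == pytest.approx(1.5)

    def test_equal_dots(self):
        rep = intensity_ratio_report([2.0, 2.0, 2.0])
        assert rep["strongest_over_weakest"] == 1.0

    def test_reference_dot_convention(self):
        rep = intensity_ratio_report([10.0, 2.0, 2.0],
                                     labels=["XY4", "Aa1", "Aa2"])
        assert rep["per_dot_over_reference"]["XY4"] == pytest.approx(5.0)

    def test_ratio_at_least_one(self, rng):
        for _ in range(20):
            vals = rng.uniform(0.5, 10.0, size=rng.integers(2, 9))
            assert intensity_ratio_report(vals)["strongest_over_weakest"] >= 1.0

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError):
            intensity_ratio_report([1.0, 0.0])


class TestPairSeparation:
    def test_identical_positions_zero(self):
        a = make_track(0, [0, 1], [[5, 5, 5], [5, 5, 5]])
        b = make_track(1, [0, 1], [[5, 5, 5], [5, 5, 5]])
        assert pair_separation(a, b).tolist() == [0.0, 0.0]

    def test_single_spot_frames_encode_zero(self):
        a = make_track(0, [0, 1, 2], [[5, 5, 5]] * 3)
        b = make_track(1, [0], [[5, 5, 7]])
        s = pair_separation(a, b)
        assert s[0] == pytest.approx(2.0)
        assert s[1] == 0.0 and s[2] == 0.0

    def test_both_missing_is_nan_not_zero(self):
        a = make_track(0, [0], [[5, 5, 5]])
        b = make_track(1, [0], [[5, 5, 6]])
        s = pair_separation(a, b, frames=[0, 1])
        assert np.isnan(s[1])

    def test_symmetry(self):
        a = make_track(0, [0, 1], [[5, 5, 5], [5, 5, 6]])
        b = make_track(1, [0, 1], [[5, 4, 5], [5, 3, 6]])
        pd.testing.assert_series_equal(pair_separation(a, b),
                                       pair_separation(b, a))


class TestStretchEpisodes:
    def test_all_zero_series_no_episodes(self):
        s = pd.Series(np.zeros(20))
        assert stretch_episodes(s) == []

    def test_relaxing_episode(self):
        vals = [0, 0, 1.2, 1.8, 2.0, 1.6, 1.1, 0, 0, 0]
        eps = stretch_episodes(pd.Series(vals), 1.0, 3)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.outcome == "relaxed"
        assert ep.max_separation_um == pytest.approx(2.0)
        assert (ep.start_frame, ep.end_frame) == (2, 6)

    def test_definitive_split(self):
        vals = [0, 0, 1.2, 1.8, 2.2, 2.4, 2.5, 2.6, 2.8, 3.0]
        eps = stretch_episodes(pd.Series(vals), 1.0, 3)
        assert len(eps) == 1 and eps[0].outcome == "definitive_split"

    def test_short_runs_ignored(self):
        vals = [0, 1.5, 1.5, 0, 0]
        assert stretch_episodes(pd.Series(vals), 1.0, 3) == []


class TestRadialSummary:
    class _Nuc:
        centroid_um = np.zeros(3)
        radius_um = 4.0

    def test_constant_radial_position(self):
        from chromotrace.metrics import radial_summary
        tr = make_track(0, range(10), [[0.0, 0.0, 3.0]] * 10)
        res = radial_summary(tr, {f: self._Nuc() for f in range(10)})
        assert res["mean"] == pytest.approx(0.75)
        assert res["sd"] == 0.0 and res["n"] == 10

    def test_peripheral_vs_central_ordering(self):
        from chromotrace.metrics import radial_summary
        nuclei = {f: self._Nuc() for f in range(10)}
        peripheral = make_track(0, range(10), [[0.0, 0.0, 3.6]] * 10)
        central = make_track(1, range(10), [[0.0, 0.0, 1.2]] * 10)
        assert radial_summary(peripheral, nuclei)["mean"] > \
            radial_summary(central, nuclei)["mean"]

    def test_late_track_warns_and_is_empty(self):
        from chromotrace.metrics import radial_summary
        tr = make_track(0, range(15, 20), [[0.0, 0.0, 1.0]] * 5)
        with pytest.warns(UserWarning):
            res = radial_summary(tr, {f: self._Nuc() for f in range(20)})
        assert res["n"] == 0 and np.isnan(res["mean"])


class TestGroupComparison:
    def test_identical_groups_t_zero_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)
        assert res["stars"] == "ns"

    def test_shifted_groups_highly_significant(self, rng):
        a = rng.normal(0.0, 1.0, 20)
        b = rng.normal(3.0, 1.0, 20)  # 3 SD shift
        res = compare_groups(a, b)
        assert res["p"] < 0.001
        assert res["stars"] == "***"

    def test_zero_variance_in_both_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("p,stars", [(0.04, "*"), (0.009, "**"),
                                         (0.0009, "***"), (0.2, "ns")])
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars
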