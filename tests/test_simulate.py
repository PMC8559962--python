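"""Synthetic movie generator: schedules, rendering, motion, determinism."""

import numpy as np
import pytest

from chromotrace.karyotype import BIVALENTS, PairingConfig, male_karyotype
from chromotrace.simulate import (AcquisitionConfig, EventSchedule,
                                  MotionConfig, simulate_anaphase,
                                  simulate_decluster_schedule, simulate_movie,
                                  simulate_stretch_schedule)
from conftest import small_acq


def dot_counts_from_schedule(schedule, times):
    """Oracle: replay the event list to count alive dots at given times."""
    alive = set(schedule.initial_dots)
    counts = []
    events = sorted(schedule.events, key=lambda e: e.time_s)
    i = 0
    for t in times:
        while i < len(events) and events[i].time_s <= t:
            e = events[i]
            if e.kind == "split":
                alive.discard(e.parent)
                alive.update(e.children)
            i += 1
        counts.append(len(alive))
    return counts


class TestDeclusterSchedule:
    def test_canonical_counts_one_through_eight(self):
        sched = simulate_decluster_schedule("canonical", [60.0] * 7, seed=0)
        times = np.arange(0, 60.0 * 8, 60.0)
        assert dot_counts_from_schedule(sched, times) == [1, 2, 3, 4, 5, 6, 7, 8]

    def test_variant_four_dot_release_before_ab_split(self):
        sched = simulate_decluster_schedule("variant_four_dot", [60.0] * 7,
                                            seed=0)
        order = [(e.parent, e.children) for e in sched.events]
        xy_release = next(i for i, (p, c) in enumerate(order) if p == "XY4")
        ab_split = next(i for i, (p, c) in enumerate(order)
                        if p == "Ab" and set(c) == {"Ab1", "Ab2"})
        aa_split = next(i for i, (p, c) in enumerate(order)
                        if p == "Aa" and set(c) == {"Aa1", "Aa2"})
        assert aa_split < xy_release < ab_split

    def test_variant_three_dot_release_before_aa_split(self):
        sched = simulate_decluster_schedule("variant_three_dot", [60.0] * 7,
                                            seed=0)
        order = [(e.parent, e.children) for e in sched.events]
        xy_release = next(i for i, (p, c) in enumerate(order) if p == "XY4")
        aa_split = next(i for i, (p, c) in enumerate(order)
                        if p == "Aa" and set(c) == {"Aa1", "Aa2"})
        assert xy_release < aa_split

    def test_zero_length_stage_jumps_count(self):
        durations = [60.0, 60.0, 60.0, 0.0, 60.0, 60.0, 60.0]
        sched = simulate_decluster_schedule("canonical", durations, seed=0)
        times = [0.0, 65.0, 125.0, 185.0, 245.0]
        counts = dot_counts_from_schedule(sched, times)
        assert 4 not in counts        # the 4-dot stage has zero duration
        assert counts[2:4] == [3, 5]  # adjacent samples jump 3 -> 5

    def test_unknown_program_rejected(self):
        with pytest.raises(ValueError):
            simulate_decluster_schedule("sideways", [60.0] * 7, seed=0)

    def test_intensity_conservation_at_every_split(self):
        sched = simulate_decluster_schedule("canonical", [60.0] * 7, seed=1)
        for e in sched.events:
            parent_i = sched.dot_intensities[e.parent]
            child_i = sum(sched.dot_intensities[c] for c in e.children)
            assert child_i == pytest.approx(parent_i)


class TestMovie:
    def test_same_seed_bit_identical(self):
        sched = simulate_decluster_schedule("canonical", [7.0] * 7, seed=2)
        acq = small_acq(n_frames=12)
        m1, _ = simulate_movie(schedule=sched, motion=MotionConfig(seed=2),
                               acq=acq, nucleus_radius_um=3.5)
        m2, _ = simulate_movie(schedule=sched, motion=MotionConfig(seed=2),
                               acq=acq, nucleus_radius_um=3.5)
        assert np.array_equal(m1.data, m2.data)

    def test_rendered_intensity_matches_truth_with_bleaching(self):
        sched = simulate_decluster_schedule("canonical", [6.0] * 7, seed=2)
        acq = small_acq(n_frames=10, gaussian_sd=0, poisson_scale=0,
                        bleach_rate=0.01, baseline=0, dot_channel_diffuse=0)
        movie, gt = simulate_movie(schedule=sched, motion=MotionConfig(seed=2),
                                   acq=acq, nucleus_radius_um=3.5)
        for f in range(movie.n_frames):
            truth = gt.dots[gt.dots.frame == f]["intensity_units"].sum()
            expected = truth * acq.photons_per_unit * (1 - 0.01) ** f
            assert movie.data[f, 1].sum() == pytest.approx(expected, rel=0.01)

    def test_trajectories_respect_confinement(self):
        sched = EventSchedule([], {"d": 2.0}, {"d": 2.0})
        motion = MotionConfig(seed=3, confinement_radius_um=0.5,
                              mean_speed_um_s=0.1)
        acq = small_acq(n_frames=40, gaussian_sd=0, poisson_scale=0)
        _, gt = simulate_movie(schedule=sched, motion=motion, acq=acq,
                               nucleus_radius_um=3.5)
        pos = gt.dots[["z_um", "y_um", "x_um"]].to_numpy()
        anchor = pos[0]
        assert np.linalg.norm(pos - anchor, axis=1).max() <= 0.5 + 1e-6

    def test_mean_step_length_matches_speed(self):
        sched = EventSchedule([], {"d": 2.0}, {"d": 2.0})
        motion = MotionConfig(seed=4, mean_speed_um_s=0.03,
                              confinement_radius_um=5.0, reversion=0.0)
        acq = small_acq(n_frames=400, z_planes=4, ny=16, nx=16,
                        gaussian_sd=0, poisson_scale=0)
        _, gt = simulate_movie(schedule=sched, motion=motion, acq=acq,
                               nucleus_radius_um=1.4)
        pos = gt.dots[["z_um", "y_um", "x_um"]].to_numpy()
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert steps.mean() == pytest.approx(0.03 * 5.0, rel=0.1)

    def test_split_half_fraction_gives_equal_children(self):
        sched = simulate_stretch_schedule([], definitive_split_time_s=50.0)
        acq = small_acq(n_frames=20, gaussian_sd=0, poisson_scale=0)
        _, gt = simulate_movie(schedule=sched, motion=MotionConfig(seed=5),
                               acq=acq, nucleus_radius_um=3.5)
        last = gt.dots[gt.dots.frame == gt.dots.frame.max()]
        vals = last["intensity_units"].to_numpy()
        assert len(vals) == 2 and vals[0] == pytest.approx(vals[1])

    def test_mutant_mode_suppresses_splits(self):
        sched = simulate_decluster_schedule("canonical", [20.0] * 7, seed=6)
        acq = small_acq(n_frames=40)
        _, gt = simulate_movie(schedule=sched, motion=MotionConfig(seed=6),
                               acq=acq, mode="condensinII_mutant",
                               nucleus_radius_um=3.5)
        assert (gt.events["kind"] == "split").sum() == 0
        assert (gt.events["kind"] == "stretch_start").sum() > 0
        assert gt.dots["dot_id"].nunique() == 1

    def test_overexpression_mode_renders_four_satellite_dots(self):
        acq = small_acq(n_frames=5)
        _, gt = simulate_movie(schedule=None, motion=MotionConfig(seed=7),
                               acq=acq, mode="overexpression",
                               nucleus_radius_um=3.5)
        assert gt.dot_count_series().tolist() == [4] * 5

    def test_events_after_movie_end_rejected(self):
        sched = simulate_decluster_schedule("canonical", [600.0] * 7, seed=0)
        acq = small_acq(n_frames=5, frame_interval_s=60.0)
        with pytest.raises(ValueError):
            simulate_movie(schedule=sched, motion=MotionConfig(seed=0),
                           acq=acq)


class TestAnaphase:
    def test_intact_bivalents_always_four_four(self):
        k = male_karyotype("G2")
        for seed in range(5):
            _, gt = simulate_anaphase(k, PairingConfig(), null_random=True,
                                      seed=seed, render=False)
            per_pole = [sum(1 for v in gt.pole_assignment.values() if v == p)
                        for p in (0, 1)]
            assert sorted(per_pole) == [4, 4]

    def test_random_univalents_match_enumeration_oracle(self):
        from chromotrace.karyotype import random_segregation_null
        k = male_karyotype("G2")
        pairing = PairingConfig({b: False for b in BIVALENTS})
        counts = {}
        n_cells = 400
        for seed in range(n_cells):
            _, gt = simulate_anaphase(k, pairing, null_random=True, seed=seed,
                                      render=False)
            a = sum(1 for v in gt.pole_assignment.values() if v == 0)
            cls = (max(a, 8 - a), min(a, 8 - a))
            counts[cls] = counts.get(cls, 0) + 1
        null = random_segregation_null(8)
        for cls, p in null.items():
            obs = counts.get(cls, 0) / n_cells
            assert abs(obs - p) < 4 * np.sqrt(p * (1 - p) / n_cells) + 0.01

    def test_seeded_truth_reproducible(self):
        k = male_karyotype("G2")
        pairing = PairingConfig({b: False for b in BIVALENTS})
        _, g1 = simulate_anaphase(k, pairing, null_random=True, seed=11,
                                  render=False)
        _, g2 = simulate_anaphase(k, pairing, null_random=True, seed=11,
                                  render=False)
        assert g1.pole_assignment == g2.pole_assignment
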