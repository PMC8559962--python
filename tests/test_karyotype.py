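"""Karyotype model: dot counts, intensities, entity counts, segregation null."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromotrace.errors import InvalidClusterError, InvalidPartitionError
from chromotrace.karyotype import (BIVALENTS, ClusterComposition,
                                   KaryotypeSpec, PairingConfig,
                                   bivalent_partition, cluster_intensity_ratio,
                                   expected_centromere_dot_count,
                                   expected_cluster_intensity,
                                   expected_entity_count,
                                   expected_telomere_dot_count, load_karyotype,
                                   male_karyotype, random_segregation_null,
                                   satellite_locus_count, save_karyotype,
                                   single_cluster_partition,
                                   sister_pair_partition, three_dot_partition)


@pytest.fixture(scope="module")
def g2():
    return male_karyotype("G2")


class TestDotCounts:
    def test_canonical_stage_partitions(self, g2):
        assert expected_centromere_dot_count(g2, single_cluster_partition(g2)) == 1
        assert expected_centromere_dot_count(g2, three_dot_partition(g2)) == 3
        assert expected_centromere_dot_count(g2, bivalent_partition(g2)) == 4
        assert expected_centromere_dot_count(g2, sister_pair_partition(g2)) == 8

    def test_incomplete_partition_rejected(self, g2):
        partial = three_dot_partition(g2)[:2]
        with pytest.raises(InvalidPartitionError):
            expected_centromere_dot_count(g2, partial)

    def test_overlapping_partition_rejected(self, g2):
        doubled = bivalent_partition(g2) + [bivalent_partition(g2)[0]]
        with pytest.raises(InvalidPartitionError):
            expected_centromere_dot_count(g2, doubled)

    def test_dot_count_equals_partition_length(self, g2):
        # oracle: direct count, for several random regroupings of the
        # sister-pair partition
        rng = np.random.default_rng(1)
        base = sister_pair_partition(g2)
        for _ in range(20):
            k = int(rng.integers(1, len(base) + 1))
            groups = [[] for _ in range(k)]
            for cl in base:
                groups[int(rng.integers(k))].extend(cl.members)
            partition = [ClusterComposition(tuple(m)) for m in groups if m]
            assert expected_centromere_dot_count(g2, partition) == len(partition)


class TestClusterIntensity:
    def test_bivalent_intensities(self, g2):
        parts = {c.label: c for c in bivalent_partition(g2)}
        assert expected_cluster_intensity(parts["chr2"], g2) == 4.0
        assert expected_cluster_intensity(parts["XY"], g2) == 6.0

    def test_xy_autosome_ratio_is_1_5(self, g2):
        parts = {c.label: c for c in bivalent_partition(g2)}
        assert cluster_intensity_ratio(parts["XY"], parts["chr2"], g2) == \
            pytest.approx(1.5)

    def test_empty_cluster_rejected(self, g2):
        with pytest.raises(InvalidClusterError):
            ClusterComposition(())

    def test_additivity_over_partitions(self, g2):
        # merged-cluster intensity equals the sum of the parts
        total = expected_cluster_intensity(single_cluster_partition(g2)[0], g2)
        for partition in (bivalent_partition(g2), three_dot_partition(g2),
                          sister_pair_partition(g2)):
            parts = sum(expected_cluster_intensity(c, g2) for c in partition)
            assert parts == pytest.approx(total)
        assert total == pytest.approx(18.0)  # 14 x 1 + 2 x 2 chromatid units


class TestEntityCount:
    def test_all_intact_gives_four_bivalents(self, g2):
        assert expected_entity_count(g2, PairingConfig()) == 4

    def test_autosome_loss_gives_seven_entities(self, g2):
        pairing = PairingConfig({"chr2": False, "chr3": False, "chr4": False,
                                 "XY": True})
        assert expected_entity_count(g2, pairing) == 7

    def test_all_lost_gives_eight_univalents(self, g2):
        pairing = PairingConfig({b: False for b in BIVALENTS})
        assert expected_entity_count(g2, pairing) == 8

    def test_pairing_must_cover_all_bivalents(self):
        with pytest.raises(ValueError):
            PairingConfig({"chr2": True})


class TestTelomereCounts:
    def test_fully_resolved_counts(self, g2):
        assert expected_telomere_dot_count(g2, "G1") == 16
        assert expected_telomere_dot_count(g2, "G2") == 32

    def test_chr4_clustering(self, g2):
        # the four telomeres of each chr4 homolog merged into one dot each
        groups = [[("chr4", c, ch, e) for ch in range(2) for e in range(2)]
                  for c in range(2)]
        assert expected_telomere_dot_count(g2, "G2", groups) == 26

    def test_unknown_telomere_rejected(self, g2):
        with pytest.raises(InvalidPartitionError):
            expected_telomere_dot_count(g2, "G1", [[("chr9", 0, 0, 0)]])

    def test_duplicated_telomere_rejected(self, g2):
        unit = ("chr2", 0, 0, 0)
        with pytest.raises(InvalidPartitionError):
            expected_telomere_dot_count(g2, "G1", [[unit], [unit]])


class TestSatellites:
    def test_1686_satellite_on_four_loci(self, g2):
        assert satellite_locus_count(g2, "sat_1686") == 4

    def test_359_satellite_only_on_x(self, g2):
        assert satellite_locus_count(g2, "sat_359") == 1


class TestSegregationNull:
    def test_eight_unit_classes(self):
        null = random_segregation_null(8)
        assert null[(4, 4)] == pytest.approx(70 / 256)
        assert null[(5, 3)] == pytest.approx(112 / 256)
        assert null[(8, 0)] == pytest.approx(2 / 256)

    def test_single_unit_trivial(self):
        assert random_segregation_null(1) == {(1, 0): 1.0}

    @pytest.mark.parametrize("n", range(1, 13))
    def test_probabilities_sum_to_one(self, n):
        assert sum(random_segregation_null(n).values()) == pytest.approx(1.0)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError):
            random_segregation_null(31, "analytic")

    def test_montecarlo_converges_to_analytic(self):
        n_cells = 100_000
        analytic = random_segregation_null(8)
        mc = random_segregation_null(8, "montecarlo", n_cells=n_cells, seed=42)
        for cls, p in analytic.items():
            bound = 3.0 * math.sqrt(p * (1 - p) / n_cells)
            assert abs(mc[cls] - p) < bound

    def test_montecarlo_requires_seed_and_cells(self):
        with pytest.raises(ValueError):
            random_segregation_null(8, "montecarlo", n_cells=10)
        with pytest.raises(ValueError):
            random_segregation_null(8, "montecarlo", seed=1)


@given(weight=st.floats(0.5, 4.0))
@settings(max_examples=20, deadline=None)
def test_configurable_y_weight_scales_ratio(weight):
    # the XY:autosome ratio follows (2 + 2w)/4 for a chrY unit weight w
    from chromotrace.karyotype import ChromosomeSpec
    base = male_karyotype("G2")
    chroms = tuple(
        c if c.name != "chrY" else ChromosomeSpec(
            "chrY", "sex", 1, centromere_unit_intensity=weight)
        for c in base.chromosomes)
    k = KaryotypeSpec(chroms, "G2")
    parts = {c.label: c for c in bivalent_partition(k)}
    expected = (2.0 + 2.0 * weight) / 4.0
    assert cluster_intensity_ratio(parts["XY"], parts["chr2"], k) == \
        pytest.approx(expected)


def test_karyotype_yaml_roundtrip(tmp_path, g2):
    path = tmp_path / "karyotype.yaml"
    save_karyotype(g2, path)
    loaded = load_karyotype(path)
    assert loaded == g2
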