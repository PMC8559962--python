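"""Male *Drosophila melanogaster* karyotype model and analytic expectations.

The male karyotype (2n = 8) comprises two large autosome pairs (chr2, chr3),
the dot chromosome pair (chr4) and the X/Y sex chromosomes.  Centromeric
fluorescence (Cenp-A/Cid fusion) is modelled as one intensity unit per
chromatid centromere, except the chrY centromere which carries twice the
unit intensity.  From this model the module derives the countable
expectations used throughout the analysis: centromere dot counts for a given
clustering, relative cluster intensities, chromosomal entity counts at
meiosis I onset under partial loss of homolog conjunction, telomere dot
counts, satellite-locus dot counts, and the random-segregation null
distribution of pole ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import yaml

from .errors import InvalidClusterError, InvalidPartitionError

__all__ = [
    "ChromosomeSpec",
    "KaryotypeSpec",
    "PairingConfig",
    "ClusterComposition",
    "male_karyotype",
    "bivalent_partition",
    "three_dot_partition",
    "sister_pair_partition",
    "expected_centromere_dot_count",
    "expected_cluster_intensity",
    "cluster_intensity_ratio",
    "expected_entity_count",
    "expected_telomere_dot_count",
    "satellite_locus_count",
    "random_segregation_null",
    "load_karyotype",
    "save_karyotype",
]

#: bivalents recognised for pairing/entity accounting; chrX and chrY form one
#: sex bivalent ("XY") held together by alternative homolog conjunction.
BIVALENTS = ("chr2", "chr3", "chr4", "XY")

ANALYTIC_ENUMERATION_CAP = 30


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome type with its copy number and fluorescence weights.

    ``centromere_unit_intensity`` is the relative Cid signal contributed by a
    single chromatid centromere (1.0 everywhere except chrY, which is 2.0).
    Every chromatid carries two telomere ends.
    """

    name: str
    size_class: str  # large_autosome | dot | sex
    copy_number: int
    centromere_unit_intensity: float = 1.0
    telomere_ends: int = 2
    satellite_labels: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.centromere_unit_intensity <= 0:
            raise ValueError("centromere_unit_intensity must be > 0")
        if self.telomere_ends != 2:
            raise ValueError("every chromatid carries exactly 2 telomere ends")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")


@dataclass(frozen=True)
class KaryotypeSpec:
    """A full karyotype plus the cell-cycle phase deciding chromatid number."""

    chromosomes: tuple[ChromosomeSpec, ...]
    ploidy_phase: str = "G2"  # G1 | G2

    def __post_init__(self):
        if self.ploidy_phase not in ("G1", "G2"):
            raise ValueError("ploidy_phase must be 'G1' or 'G2'")

    @property
    def chromatids_per_chromosome(self) -> int:
        return 2 if self.ploidy_phase == "G2" else 1

    @property
    def n_chromosomes(self) -> int:
        return sum(c.copy_number for c in self.chromosomes)

    def chromosome(self, name: str) -> ChromosomeSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def centromere_units(self) -> list[tuple[str, int, int]]:
        """Every chromatid centromere as a (chromosome, copy, chromatid) unit."""
        k = self.chromatids_per_chromosome
        return [
            (c.name, copy, chromatid)
            for c in self.chromosomes
            for copy in range(c.copy_number)
            for chromatid in range(k)
        ]

    def telomere_units(self) -> list[tuple[str, int, int, int]]:
        """Every telomere end as a (chromosome, copy, chromatid, end) unit."""
        k = self.chromatids_per_chromosome
        return [
            (c.name, copy, chromatid, end)
            for c in self.chromosomes
            for copy in range(c.copy_number)
            for chromatid in range(k)
            for end in range(c.telomere_ends)
        ]

    def with_phase(self, phase: str) -> "KaryotypeSpec":
        return KaryotypeSpec(self.chromosomes, phase)


@dataclass(frozen=True)
class PairingConfig:
    """Per-bivalent conjunction state at meiosis I onset.

    ``conjunction_intact`` maps each bivalent name to whether homolog
    conjunction still holds it together (an intact bivalent is one entity;
    a disrupted one contributes two univalents).  ``heterolog_association``
    and ``sister_resolution`` flags are carried for simulator scenarios.
    """

    conjunction_intact: dict = field(
        default_factory=lambda: {b: True for b in BIVALENTS}
    )
    heterolog_association_intact: bool = False
    sister_resolution: bool = True

    def __post_init__(self):
        missing = [b for b in BIVALENTS if b not in self.conjunction_intact]
        if missing:
            raise ValueError(f"pairing must cover all bivalents; missing {missing}")


@dataclass(frozen=True)
class ClusterComposition:
    """One fluorescent dot as a set of (chromosome, copy, chromatid_count) members."""

    members: tuple[tuple[str, int, int], ...]
    label: str = ""

    def __post_init__(self):
        if not self.members:
            raise InvalidClusterError("cluster has no members")
        for name, copy, n_chromatids in self.members:
            if n_chromatids < 1:
                raise InvalidClusterError(
                    f"member ({name},{copy}) with chromatid count {n_chromatids}"
                )


def male_karyotype(phase: str = "G2") -> KaryotypeSpec:
    """The default male melanogaster karyotype (2n = 8, chrY centromere 2x)."""
    chromosomes = (
        ChromosomeSpec("chr2", "large_autosome", 2,
                       satellite_labels=frozenset({"sat_1686"})),
        ChromosomeSpec("chr3", "large_autosome", 2,
                       satellite_labels=frozenset({"sat_1686"})),
        ChromosomeSpec("chr4", "dot", 2),
        ChromosomeSpec("chrX", "sex", 1, satellite_labels=frozenset({"sat_359"})),
        ChromosomeSpec("chrY", "sex", 1, centromere_unit_intensity=2.0),
    )
    return KaryotypeSpec(chromosomes, phase)


# ---------------------------------------------------------------------------
# canonical clusterings


def _full_chromosome_member(karyotype, name, copy):
    return (name, copy, karyotype.chromatids_per_chromosome)


def bivalent_partition(karyotype: KaryotypeSpec) -> list[ClusterComposition]:
    """One cluster per bivalent: chr2, chr3, chr4 and the XY pair."""
    parts = []
    for biv in ("chr2", "chr3", "chr4"):
        parts.append(ClusterComposition(
            tuple(_full_chromosome_member(karyotype, biv, c) for c in range(2)),
            label=biv,
        ))
    parts.append(ClusterComposition(
        (_full_chromosome_member(karyotype, "chrX", 0),
         _full_chromosome_member(karyotype, "chrY", 0)),
        label="XY",
    ))
    return parts


def three_dot_partition(karyotype: KaryotypeSpec) -> list[ClusterComposition]:
    """The three-dot stage {Aa, Ab, XY4}: each large autosome bivalent alone,
    sex chromosomes and chr4 merged into one cluster."""
    aa = ClusterComposition(
        tuple(_full_chromosome_member(karyotype, "chr2", c) for c in range(2)),
        label="Aa",
    )
    ab = ClusterComposition(
        tuple(_full_chromosome_member(karyotype, "chr3", c) for c in range(2)),
        label="Ab",
    )
    xy4 = ClusterComposition(
        (_full_chromosome_member(karyotype, "chrX", 0),
         _full_chromosome_member(karyotype, "chrY", 0),
         _full_chromosome_member(karyotype, "chr4", 0),
         _full_chromosome_member(karyotype, "chr4", 1)),
        label="XY4",
    )
    return [aa, ab, xy4]


def single_cluster_partition(karyotype: KaryotypeSpec) -> list[ClusterComposition]:
    """All centromeres merged into one cluster (earliest stage)."""
    members = tuple(
        _full_chromosome_member(karyotype, c.name, copy)
        for c in karyotype.chromosomes
        for copy in range(c.copy_number)
    )
    return [ClusterComposition(members, label="all")]


def sister_pair_partition(karyotype: KaryotypeSpec) -> list[ClusterComposition]:
    """Every sister-centromere pair (one homolog copy) as its own cluster."""
    return [
        ClusterComposition(
            ((c.name, copy, karyotype.chromatids_per_chromosome),),
            label=f"{c.name}.{copy}",
        )
        for c in karyotype.chromosomes
        for copy in range(c.copy_number)
    ]


# ---------------------------------------------------------------------------
# expectations


def _validate_partition(karyotype: KaryotypeSpec,
                        partition: Sequence[ClusterComposition]) -> None:
    k = karyotype.chromatids_per_chromosome
    seen: dict[tuple[str, int], int] = {}
    for cluster in partition:
        for name, copy, n in cluster.members:
            chrom = karyotype.chromosome(name)  # raises KeyError if unknown
            if copy >= chrom.copy_number:
                raise InvalidPartitionError(f"no homolog copy {copy} of {name}")
            seen[(name, copy)] = seen.get((name, copy), 0) + n
    for c in karyotype.chromosomes:
        for copy in range(c.copy_number):
            got = seen.pop((c.name, copy), 0)
            if got != k:
                raise InvalidPartitionError(
                    f"({c.name}, copy {copy}): {got} chromatids covered, expected {k}"
                )
    if seen:
        raise InvalidPartitionError(f"unexpected members {sorted(seen)}")


def expected_centromere_dot_count(karyotype: KaryotypeSpec,
                                  partition: Sequence[ClusterComposition]) -> int:
    """Number of centromere dots for a clustering that partitions all units."""
    _validate_partition(karyotype, partition)
    return len(partition)


def expected_cluster_intensity(cluster: ClusterComposition,
                               karyotype: KaryotypeSpec) -> float:
    """Expected relative Cid intensity of one dot: sum of unit weights x chromatids."""
    if not cluster.members:
        raise InvalidClusterError("empty cluster")
    total = 0.0
    for name, _copy, n_chromatids in cluster.members:
        total += karyotype.chromosome(name).centromere_unit_intensity * n_chromatids
    return total


def cluster_intensity_ratio(a: ClusterComposition, b: ClusterComposition,
                            karyotype: KaryotypeSpec) -> float:
    """Intensity ratio of cluster ``a`` over cluster ``b``."""
    return expected_cluster_intensity(a, karyotype) / expected_cluster_intensity(b, karyotype)


def expected_entity_count(karyotype: KaryotypeSpec, pairing: PairingConfig) -> int:
    """Separate chromosomal entities at M I onset.

    Each bivalent with intact homolog conjunction counts as one entity; a
    disrupted bivalent contributes its two univalents.
    """
    return sum(1 if pairing.conjunction_intact[b] else 2 for b in BIVALENTS)


def expected_telomere_dot_count(
    karyotype: KaryotypeSpec,
    phase: str | None = None,
    clustering: Sequence[Iterable[tuple[str, int, int, int]]] = (),
) -> int:
    """Telomere dot count for a phase and an optional clustering of ends.

    With no clustering every telomere end resolves as its own dot
    (chromosomes x 2 ends x chromatids).  Each clustering group merges its
    member ends into a single dot; groups must be disjoint and reference
    existing ends.
    """
    kary = karyotype if phase is None else karyotype.with_phase(phase)
    units = set(kary.telomere_units())
    total = len(units)
    used: set = set()
    n_grouped = 0
    for group in clustering:
        g = list(group)
        for u in g:
            if u not in units:
                raise InvalidPartitionError(f"unknown telomere unit {u}")
            if u in used:
                raise InvalidPartitionError(f"telomere unit {u} in two groups")
            used.add(u)
        n_grouped += len(g)
        if not g:
            raise InvalidPartitionError("empty telomere group")
    return total - n_grouped + len(list(clustering))


def satellite_locus_count(karyotype: KaryotypeSpec, label: str) -> int:
    """Number of satellite-repeat loci carrying ``label`` (one per homolog copy).

    When all pairing and heterologous associations are disrupted, each locus
    resolves as one TALE-light dot; e.g. the 1.686 satellite sits on both
    chr2 and chr3, hence 4 dots.
    """
    return sum(c.copy_number for c in karyotype.chromosomes
               if label in c.satellite_labels)


# ---------------------------------------------------------------------------
# random-segregation null


def random_segregation_null(
    n_units: int,
    mode: str = "analytic",
    n_cells: int | None = None,
    seed: int | None = None,
) -> dict[tuple[int, int], float]:
    """Distribution of unordered pole ratios under random segregation.

    Each of ``n_units`` univalents independently picks one of two poles with
    probability 1/2.  Ratios are reported unordered, i.e. class ``(a, b)``
    with ``a >= b`` and ``a + b = n_units``.

    ``analytic`` enumerates all 2**n assignments exactly (capped at n = 30);
    ``montecarlo`` draws ``n_cells`` cells with the given ``seed`` and
    returns empirical class frequencies.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    classes = [(n_units - b, b) for b in range(n_units // 2 + 1)]
    if mode == "analytic":
        if n_units > ANALYTIC_ENUMERATION_CAP:
            raise ValueError(
                f"analytic enumeration refused for n_units > {ANALYTIC_ENUMERATION_CAP}"
            )
        denom = 2 ** n_units
        probs = {}
        for a, b in classes:
            ways = math.comb(n_units, a)
            if a != b:
                ways *= 2
            probs[(a, b)] = ways / denom
        return probs
    if mode == "montecarlo":
        if not n_cells or n_cells < 1:
            raise ValueError("montecarlo mode requires n_cells >= 1")
        if seed is None:
            raise ValueError("montecarlo mode requires a seed")
        rng = np.random.default_rng(seed)
        at_pole_1 = rng.binomial(n_units, 0.5, size=n_cells)
        a = np.maximum(at_pole_1, n_units - at_pole_1)
        freqs = {cls: 0.0 for cls in classes}
        values, counts = np.unique(a, return_counts=True)
        for v, c in zip(values, counts):
            freqs[(int(v), n_units - int(v))] = c / n_cells
        return freqs
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# serialization (human-editable YAML)


def save_karyotype(karyotype: KaryotypeSpec, path) -> None:
    doc = {
        "ploidy_phase": karyotype.ploidy_phase,
        "chromosomes": [
            {
                "name": c.name,
                "size_class": c.size_class,
                "copy_number": c.copy_number,
                "centromere_unit_intensity": c.centromere_unit_intensity,
                "telomere_ends": c.telomere_ends,
                "satellite_labels": sorted(c.satellite_labels),
            }
            for c in karyotype.chromosomes
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_karyotype(path) -> KaryotypeSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    chromosomes = tuple(
        ChromosomeSpec(
            name=c["name"],
            size_class=c["size_class"],
            copy_number=int(c["copy_number"]),
            centromere_unit_intensity=float(c.get("centromere_unit_intensity", 1.0)),
            telomere_ends=int(c.get("telomere_ends", 2)),
            satellite_labels=frozenset(c.get("satellite_labels", [])),
        )
        for c in doc["chromosomes"]
    )
    return KaryotypeSpec(chromosomes, doc.get("ploidy_phase", "G2"))
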