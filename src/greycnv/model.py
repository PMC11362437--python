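"""Core domain objects for the Grey-locus tandem CNV.

The horse *Grey* locus is a tandem copy number variant of a 4.6 kb sequence in
*STX17* intron 6.  Alleles form a series G1/G2/G3: the wild-type allele carries
one copy of the unit, G2 two tandem copies (slow greying) and G3 three (fast
greying).  A diploid genotype is a pair of such alleles; assays such as read
depth and droplet digital PCR measure only the *total* copy number (2-6
observed), which is why per-chromosome alleles must be deduced from pedigrees
or typed directly from long spanning reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

__all__ = [
    "NON_GREY",
    "SLOW",
    "FAST",
    "UNKNOWN",
    "GreyAllele",
    "CnvGenotype",
    "phenotype_from_genotype",
    "Individual",
    "Pedigree",
    "CnvLocusModel",
    "GenomicInterval",
    "SnpMatrix",
]

# Phenotype classes for greying speed.
NON_GREY = "non_grey"
SLOW = "slow"
FAST = "fast"
UNKNOWN = "unknown"

PHENOTYPES = frozenset({NON_GREY, SLOW, FAST, UNKNOWN})


@dataclass(frozen=True, order=True)
class GreyAllele:
    """One chromosome's allele: the number of tandem copies of the unit.

    ``copies == 1`` is wild type (G1); two copies is the slow-greying G2 and
    three the fast-greying G3 allele.
    """

    copies: int

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"allele copies must be >= 1, got {self.copies}")

    @property
    def label(self) -> str:
        return f"G{self.copies}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class CnvGenotype:
    """Diploid genotype: one allele per chromosome."""

    maternal: GreyAllele
    paternal: GreyAllele

    @classmethod
    def from_copies(cls, maternal: int, paternal: int) -> "CnvGenotype":
        return cls(GreyAllele(maternal), GreyAllele(paternal))

    @property
    def total_copies(self) -> int:
        return self.maternal.copies + self.paternal.copies

    @property
    def max_allele_copies(self) -> int:
        return max(self.maternal.copies, self.paternal.copies)

    def as_sorted_tuple(self) -> tuple[int, int]:
        """Unordered representation, larger allele first (e.g. ``(3, 2)``)."""
        a, b = self.maternal.copies, self.paternal.copies
        return (a, b) if a >= b else (b, a)

    @property
    def label(self) -> str:
        hi, lo = self.as_sorted_tuple()
        return f"G{hi}/G{lo}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def phenotype_from_genotype(genotype: CnvGenotype) -> str:
    """Greying-speed phenotype implied by a diploid CNV genotype.

    Dominance of the largest allele: any allele with >= 3 copies gives fast
    greying, a largest allele of exactly 2 copies gives slow greying, and two
    wild-type alleles give a non-grey horse.
    """
    top = genotype.max_allele_copies
    if top >= 3:
        return FAST
    if top == 2:
        return SLOW
    return NON_GREY


@dataclass
class Individual:
    """A pedigree member.

    ``measured_total_copies`` is the diploid copy number from an assay (read
    depth or ddPCR); ``true_genotype`` is only populated by the simulator and
    never consulted by inference code.
    """

    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    phenotype: str = UNKNOWN
    measured_total_copies: Optional[int] = None
    true_genotype: Optional[CnvGenotype] = None
    generation: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


@dataclass
class MutationRecord:
    """A de-novo copy-number change during one meiosis (simulator ground truth)."""

    child_id: str
    parent_id: str
    from_copies: int
    to_copies: int

    @property
    def direction(self) -> str:
        return "contraction" if self.to_copies < self.from_copies else "expansion"


class Pedigree:
    """Ordered collection of individuals; parents precede their children."""

    def __init__(self, individuals: Iterable[Individual] = ()) -> None:
        self._order: list[str] = []
        self._by_id: dict[str, Individual] = {}
        self.mutation_events: list[MutationRecord] = []
        for ind in individuals:
            self.add(ind)

    def add(self, ind: Individual) -> None:
        if ind.id in self._by_id:
            raise ValueError(f"duplicate individual id {ind.id!r}")
        for pid in (ind.sire_id, ind.dam_id):
            if pid is not None and pid not in self._by_id:
                raise ValueError(
                    f"parent {pid!r} of {ind.id!r} must be added before the child"
                )
        self._by_id[ind.id] = ind
        self._order.append(ind.id)

    def __iter__(self) -> Iterator[Individual]:
        return (self._by_id[i] for i in self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    @property
    def ids(self) -> list[str]:
        return list(self._order)

    def children_of(self, parent_id: str) -> list[Individual]:
        return [
            ind
            for ind in self
            if parent_id in (ind.sire_id, ind.dam_id)
        ]


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval, 0-based (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class CnvLocusModel:
    """Geometry of the CNV locus and of captured spanning fragments.

    A captured fragment consists of the flanking sequence (both sides pooled,
    ``flank_length_bp``) plus ``k`` copies of the duplicated unit, so a
    wild-type haplotype yields a ~7.7 kb fragment, a duplication ~12.3 kb and a
    triplication ~16.9 kb at the genomic defaults (unit 4.6 kb, flanks 3.1 kb).
    """

    unit_length_bp: int = 4600
    flank_length_bp: int = 3100
    cnv_interval: GenomicInterval = field(
        default_factory=lambda: GenomicInterval("chr25", 6_625_000, 6_629_600)
    )

    def __post_init__(self) -> None:
        if self.unit_length_bp < 1 or self.flank_length_bp < 0:
            raise ValueError("unit/flank lengths must be positive")

    def expected_fragment_length(self, copies: int) -> int:
        if copies < 1:
            raise ValueError("copies must be >= 1")
        return self.flank_length_bp + copies * self.unit_length_bp

    @classmethod
    def scaled_down(cls, factor: int = 10) -> "CnvLocusModel":
        """Desk-scale locus (unit 460 bp, flank 310 bp by default) for fast
        simulation; the length *ratios* and hence all classification logic are
        unchanged."""
        return cls(
            unit_length_bp=4600 // factor,
            flank_length_bp=3100 // factor,
            cnv_interval=GenomicInterval("chr25", 6_625_000, 6_625_000 + 4600 // factor),
        )


@dataclass
class SnpMatrix:
    """Biallelic genotypes (0/1/2 alt-allele dosage, -1 missing) at ordered
    positions, one column per sample."""

    chrom: str
    positions: "np.ndarray"  # (n_sites,) increasing
    samples: list[str]
    genotypes: "np.ndarray"  # (n_sites, n_samples) int8/int16

    def __post_init__(self) -> None:
        import numpy as np

        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError(
                "genotype matrix shape does not match positions x samples"
            )
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in matrix") from None

    def column(self, sample: str) -> "np.ndarray":
        return self.genotypes[:, self.sample_index(sample)]
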