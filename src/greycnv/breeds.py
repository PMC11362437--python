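"""Breed-level genotype deduction and allele frequencies from copy-number
histograms.

A ddPCR screen reports only total diploid copy number (2-6).  Totals 2, 3, 5
and 6 map uniquely to G1/G1, G1/G2, G2/G3 and G3/G3; a total of 4 could be
either G1/G3 or G2/G2.  Under the assumption that no G2/G2 homozygote is
present (justified by the low frequency implied by the number of G1/G2 and
G2/G3 heterozygotes), all 4-copy horses are counted as G1/G3 and the allele
frequencies follow by allele counting:

    fG2 = (n3 + n5) / 2n      fG3 = (n4 + n5 + 2 n6) / 2n

These are acknowledged to be biased when G2/G2 individuals do exist (fG2 is
then underestimated).  Hardy-Weinberg expectations over total copy number are
provided for simulation round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BreedCnvTable",
    "AlleleFrequencies",
    "deduce_genotype_counts",
    "allele_frequencies",
    "hwe_expected_cn_distribution",
    "breed_frequency_report",
    "PUBLISHED_BREED_TABLES",
    "PUBLISHED_FREQUENCIES",
]


@dataclass(frozen=True)
class BreedCnvTable:
    """Per-breed histogram of total copy number 2..6."""

    breed: str
    n2: int
    n3: int
    n4: int
    n5: int
    n6: int

    def __post_init__(self) -> None:
        counts = (self.n2, self.n3, self.n4, self.n5, self.n6)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("empty breed table")

    @property
    def n(self) -> int:
        return self.n2 + self.n3 + self.n4 + self.n5 + self.n6

    @classmethod
    def from_counts(cls, breed: str, counts: Mapping[int, int]) -> "BreedCnvTable":
        extra = set(counts) - {2, 3, 4, 5, 6}
        if extra:
            # No germ-line allele beyond three copies has been observed; a
            # total above 6 would require one.
            raise ValueError(
                f"total copy numbers outside 2..6 not supported: {sorted(extra)}"
            )
        return cls(
            breed=breed,
            n2=counts.get(2, 0),
            n3=counts.get(3, 0),
            n4=counts.get(4, 0),
            n5=counts.get(5, 0),
            n6=counts.get(6, 0),
        )


@dataclass(frozen=True)
class AlleleFrequencies:
    fG1: float
    fG2: float
    fG3: float

    def __post_init__(self) -> None:
        for f in (self.fG1, self.fG2, self.fG3):
            if not 0.0 <= f <= 1.0 + 1e-12:
                raise ValueError("allele frequencies must lie in [0, 1]")
        if abs(self.fG1 + self.fG2 + self.fG3 - 1.0) > 1e-9:
            raise ValueError("allele frequencies must sum to 1")

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        """Report-style rounding, half away from zero."""

        def _r(x: float) -> float:
            scale = 10**ndigits
            return np.floor(x * scale + 0.5) / scale

        return (_r(self.fG1), _r(self.fG2), _r(self.fG3))


def deduce_genotype_counts(table: BreedCnvTable) -> dict[str, int]:
    """Genotype counts under the no-G2/G2 assumption (all 4-copy horses are
    G1/G3)."""
    mapping = {
        "G1/G1": table.n2,
        "G1/G2": table.n3,
        "G1/G3": table.n4,
        "G2/G3": table.n5,
        "G3/G3": table.n6,
    }
    return {g: c for g, c in mapping.items() if c > 0}


def allele_frequencies(table: BreedCnvTable) -> AlleleFrequencies:
    """Allele-counting estimates of fG2 and fG3 (fG1 by complement)."""
    two_n = 2 * table.n
    fG2 = (table.n3 + table.n5) / two_n
    fG3 = (table.n4 + table.n5 + 2 * table.n6) / two_n
    return AlleleFrequencies(fG1=1.0 - fG2 - fG3, fG2=fG2, fG3=fG3)


def hwe_expected_cn_distribution(
    freqs: AlleleFrequencies, n: float
) -> dict[int, float]:
    """Expected counts by total copy number under Hardy-Weinberg equilibrium.

    Genotype probabilities are products of allele frequencies (2 f_i f_j off
    the diagonal); totals pool genotypes, so 4 copies combines G1/G3 with
    G2/G2.
    """
    f = {1: freqs.fG1, 2: freqs.fG2, 3: freqs.fG3}
    out = {t: 0.0 for t in range(2, 7)}
    for i in (1, 2, 3):
        for j in (1, 2, 3):
            if j < i:
                continue
            prob = f[i] ** 2 if i == j else 2 * f[i] * f[j]
            out[i + j] += prob * n
    return out


def _table(breed: str, *counts: int) -> BreedCnvTable:
    return BreedCnvTable(breed, *counts)


#: The published across-breed ddPCR screen (counts of horses with total copy
#: number 2..6) for the eight breeds in which both variant alleles were
#: detected.  These printed counts are inputs to the frequency machinery.
PUBLISHED_BREED_TABLES: tuple[BreedCnvTable, ...] = (
    _table("Andalusian", 25, 8, 40, 1, 9),
    _table("Connemara Pony", 23, 6, 49, 3, 9),
    _table("Miniature Horse", 25, 1, 15, 0, 0),
    _table("Mangalarga Marchador", 0, 1, 8, 0, 0),
    _table("Mustang", 3, 2, 8, 0, 0),
    _table("Quarter Horse", 141, 0, 284, 1, 13),
    _table("Tennessee Walking Horse", 16, 2, 23, 0, 4),
    _table("Welsh Pony", 7, 1, 25, 0, 3),
)

#: Allele frequencies as printed alongside the counts (two decimals).
PUBLISHED_FREQUENCIES: dict[str, tuple[float, float]] = {
    "Andalusian": (0.05, 0.36),
    "Connemara Pony": (0.05, 0.39),
    "Miniature Horse": (0.01, 0.18),
    "Mangalarga Marchador": (0.06, 0.44),
    "Mustang": (0.08, 0.31),
    "Quarter Horse": (0.00, 0.35),
    "Tennessee Walking Horse": (0.02, 0.34),
    "Welsh Pony": (0.01, 0.43),
}


def breed_frequency_report(
    tables: tuple[BreedCnvTable, ...] = PUBLISHED_BREED_TABLES,
) -> pd.DataFrame:
    """Frequency table (breed, n, fG2, fG3 rounded to two decimals)."""
    rows = []
    for t in tables:
        f = allele_frequencies(t)
        _, fg2, fg3 = f.rounded(2)
        rows.append({"breed": t.breed, "n": t.n, "fG2": fg2, "fG3": fg3})
    return pd.DataFrame(rows)
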