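"""Exact small-sample association statistics.

Chi-square goodness of fit (no continuity correction), the two-sided Fisher
exact test by the point-probability method, a per-SNP dominance-model
association scan (carrier vs non-carrier status against a binary phenotype),
and the Bonferroni significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import SnpMatrix

__all__ = [
    "TestResult",
    "ContingencyTable2x2",
    "chi2_goodness_of_fit",
    "fisher_exact_two_sided",
    "gwas_dominance_scan",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class TestResult:
    p_value: float
    statistic: Optional[float] = None
    df: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]; rows are phenotype classes, columns carrier
    status in the dominance scan."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def chi2_goodness_of_fit(
    observed_counts: Sequence[int],
    expected_proportions: Sequence[float],
) -> TestResult:
    """Pearson goodness-of-fit test, no continuity correction.

    ``statistic = sum((O - E)^2 / E)`` with ``E = n * p``, df = categories - 1,
    upper-tail chi-square p-value.
    """
    obs = np.asarray(observed_counts, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if obs.shape != props.shape:
        raise ValueError("observed counts and expected proportions differ in length")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = obs.sum() * props
    if (expected <= 0).any():
        raise ValueError("zero expected count")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = len(obs) - 1
    p = float(sps.chi2.sf(statistic, df))
    return TestResult(p_value=p, statistic=statistic, df=df, name="chi2_gof")


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test.

    With margins fixed, sums the hypergeometric probabilities of every table
    whose point probability does not exceed that of the observed table (the
    construction used by the common implementations).  Degenerate margins give
    p = 1.
    """
    p = float(sps.fisher_exact(table.as_array(), alternative="two-sided")[1])
    return TestResult(p_value=min(p, 1.0), name="fisher_exact")


def gwas_dominance_scan(
    snps: SnpMatrix,
    phenotypes: Sequence[str],
    case_class: Optional[str] = None,
) -> pd.DataFrame:
    """Per-SNP Fisher exact association under a dominance model.

    Each sample is encoded as a carrier (genotype >= 1) or non-carrier, and a
    2x2 carrier-status x phenotype-class table is tested per site.  Sites
    monomorphic in carrier status (all carriers or all non-carriers among
    phenotyped, genotyped samples) get p = 1; missing genotypes (-1) are
    excluded per site.  Returns a frame with columns ``chrom, pos, p``.
    """
    phen = np.asarray(phenotypes, dtype=object)
    if len(phen) != len(snps.samples):
        raise ValueError("one phenotype per sample is required")
    classes = sorted(set(phen))
    if len(classes) != 2:
        raise ValueError(f"exactly two phenotype classes required, got {classes}")
    if case_class is None:
        case_class = classes[0]
    is_case = phen == case_class

    pvals = np.ones(snps.n_sites)
    gmat = snps.genotypes
    for i in range(snps.n_sites):
        g = gmat[i]
        ok = g >= 0
        carrier = g[ok] >= 1
        case = is_case[ok]
        a = int((carrier & case).sum())
        b = int((~carrier & case).sum())
        c = int((carrier & ~case).sum())
        d = int((~carrier & ~case).sum())
        if a + b + c + d == 0:
            continue
        pvals[i] = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
    return pd.DataFrame(
        {"chrom": snps.chrom, "pos": snps.positions, "p": pvals}
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold ``alpha / n_tests``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
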