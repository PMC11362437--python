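"""Identity-by-descent scanning and homozygosity analysis.

Two haplotypes that descend from a recent common ancestor cannot be opposite
homozygotes at any site inside the shared segment, so the fraction of
opposite-homozygote calls between two samples, in sliding windows of SNPs,
drops to zero across an IBD region.  This module implements that scan, the
heterozygous-comparator variant used when the reference individual is
compared against a compound heterozygote, interval calling on the window
fractions, and pileup-based nucleotide diversity with the minor-read filter
used to suppress long-read basecalling noise, from which runs of
homozygosity (ROH) are called.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import GenomicInterval, SnpMatrix

__all__ = [
    "IbdScanResult",
    "PileupTable",
    "DiversityTrack",
    "opposite_homozygote_fractions",
    "het_comparison_fractions",
    "call_ibd_intervals",
    "pileup_diversity",
    "call_roh",
]


@dataclass
class IbdScanResult:
    """Sliding-window fractions over ordered SNPs for one sample pair."""

    chrom: str
    window_start_pos: np.ndarray  # bp position of first SNP in window
    window_end_pos: np.ndarray  # bp position of last SNP in window (inclusive)
    fractions: np.ndarray
    pair: tuple[str, str]
    window_snps: int
    step_snps: int
    kind: str = "opposite_homozygote"

    def __post_init__(self) -> None:
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("window fractions must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.fractions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.window_start_pos,
                "end": self.window_end_pos,
                "fraction": self.fractions,
            }
        )


def _window_fractions(
    indicator: np.ndarray,
    positions: np.ndarray,
    window_snps: int,
    step_snps: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = len(indicator)
    if n < window_snps:
        raise ValueError(
            f"need at least {window_snps} comparable sites, got {n}"
        )
    csum = np.concatenate([[0], np.cumsum(indicator)])
    starts = np.arange(0, n - window_snps + 1, step_snps)
    counts = csum[starts + window_snps] - csum[starts]
    fractions = counts / window_snps
    return positions[starts], positions[starts + window_snps - 1], fractions


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sites where both samples have a called genotype."""
    return (a >= 0) & (b >= 0)


def opposite_homozygote_fractions(
    reference_sample: str,
    other_sample: str,
    snps: SnpMatrix,
    window_snps: int = 100,
    step_snps: int = 1,
) -> IbdScanResult:
    """Sliding-window fraction of opposite-homozygote calls between two samples.

    A site counts when one sample is homozygous reference (0) and the other
    homozygous alternate (2); such sites are incompatible with the pair
    sharing both haplotypes IBD.  Missing genotypes are excluded and windows
    are defined over the remaining comparable sites.
    """
    a = snps.column(reference_sample)
    b = snps.column(other_sample)
    ok = _comparable(a, b)
    a, b, pos = a[ok], b[ok], snps.positions[ok]
    opposite = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    w_start, w_end, frac = _window_fractions(opposite, pos, window_snps, step_snps)
    return IbdScanResult(
        chrom=snps.chrom,
        window_start_pos=w_start,
        window_end_pos=w_end,
        fractions=frac,
        pair=(reference_sample, other_sample),
        window_snps=window_snps,
        step_snps=step_snps,
    )


def het_comparison_fractions(
    reference_sample: str,
    het_sample: str,
    snps: SnpMatrix,
    window_snps: int = 100,
    step_snps: int = 1,
) -> tuple[IbdScanResult, IbdScanResult]:
    """Opposite-homozygote and heterozygous-difference tracks for a compound
    heterozygote.

    When the comparison individual carries two different CNV haplotypes, the
    homozygous-difference track reflects divergence from the haplotype it
    shares with the reference and the heterozygous-difference track (het in
    the comparison sample, homozygous in the reference) divergence from the
    other haplotype.
    """
    a = snps.column(reference_sample)
    b = snps.column(het_sample)
    ok = _comparable(a, b)
    a, b, pos = a[ok], b[ok], snps.positions[ok]

    opposite = ((a == 0) & (b == 2)) | ((a == 2) & (b == 0))
    het_diff = ((a == 0) | (a == 2)) & (b == 1)

    w_start, w_end, frac = _window_fractions(opposite, pos, window_snps, step_snps)
    hom_track = IbdScanResult(
        chrom=snps.chrom,
        window_start_pos=w_start,
        window_end_pos=w_end,
        fractions=frac,
        pair=(reference_sample, het_sample),
        window_snps=window_snps,
        step_snps=step_snps,
        kind="opposite_homozygote",
    )
    w_start, w_end, frac = _window_fractions(het_diff, pos, window_snps, step_snps)
    het_track = IbdScanResult(
        chrom=snps.chrom,
        window_start_pos=w_start,
        window_end_pos=w_end,
        fractions=frac,
        pair=(reference_sample, het_sample),
        window_snps=window_snps,
        step_snps=step_snps,
        kind="heterozygous_difference",
    )
    return hom_track, het_track


def call_ibd_intervals(
    scan: IbdScanResult, max_fraction: float = 0.0
) -> list[GenomicInterval]:
    """Maximal runs of windows with fraction <= ``max_fraction``, merged into
    bp intervals (end exclusive, spanning first to last SNP of the run)."""
    low = scan.fractions <= max_fraction
    intervals: list[GenomicInterval] = []
    i = 0
    n = len(low)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        intervals.append(
            GenomicInterval(
                scan.chrom,
                int(scan.window_start_pos[i]),
                int(scan.window_end_pos[j]) + 1,
            )
        )
        i = j + 1
    return intervals


@dataclass
class PileupTable:
    """Per-site base counts: columns chrom, pos, depth, A, C, G, T."""

    frame: pd.DataFrame

    REQUIRED = ("chrom", "pos", "depth", "A", "C", "G", "T")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"pileup table missing columns: {missing}")
        counts = self.frame[["A", "C", "G", "T"]].to_numpy()
        depth = self.frame["depth"].to_numpy()
        if (depth < 0).any():
            raise ValueError("negative depth")
        if (counts.sum(axis=1) > depth).any():
            raise ValueError("base counts exceed depth")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class DiversityTrack:
    """Windowed mean per-site non-major allele fraction."""

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    window_bp: int

    def __post_init__(self) -> None:
        if (self.values < 0).any():
            raise ValueError("diversity values must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "diversity": self.values,
            }
        )


def pileup_diversity(
    pileup: PileupTable,
    min_minor_reads: int = 3,
    window_bp: int = 500_000,
) -> DiversityTrack:
    """Windowed nucleotide diversity from pileup base counts.

    The per-site non-major fraction ``(depth - major_count) / depth`` is set
    to zero whenever fewer than ``min_minor_reads`` reads support a non-major
    allele (suppressing basecalling noise); zero-depth sites are skipped and
    windows of ``window_bp`` average the surviving per-site values.
    """
    df = pileup.frame
    pos = df["pos"].to_numpy()
    if len(pos) > 1 and not (np.diff(pos) > 0).all():
        raise ValueError("pileup must be sorted by position")
    depth = df["depth"].to_numpy(dtype=float)
    counts = df[["A", "C", "G", "T"]].to_numpy(dtype=float)
    keep = depth > 0
    pos, depth, counts = pos[keep], depth[keep], counts[keep]

    major = counts.max(axis=1)
    non_major = depth - major
    frac = np.where(non_major <= min_minor_reads - 1, 0.0, non_major / depth)

    chrom = str(df["chrom"].iloc[0]) if len(df) else "chrom"
    if len(pos) == 0:
        return DiversityTrack(chrom, np.array([]), np.array([]), np.array([]), window_bp)
    first = (int(pos[0]) // window_bp) * window_bp
    last = int(pos[-1]) // window_bp * window_bp + window_bp
    starts = np.arange(first, last, window_bp, dtype=np.int64)
    idx = (pos - first) // window_bp
    sums = np.bincount(idx, weights=frac, minlength=len(starts))
    ns = np.bincount(idx, minlength=len(starts))
    with np.errstate(invalid="ignore"):
        values = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    ok = ns > 0
    return DiversityTrack(
        chrom=chrom,
        starts=starts[ok],
        ends=(starts + window_bp)[ok],
        values=values[ok],
        window_bp=window_bp,
    )


def call_roh(
    track: DiversityTrack, max_diversity: float = 1e-4
) -> list[GenomicInterval]:
    """Runs of homozygosity: maximal runs of consecutive windows whose mean
    diversity is at most ``max_diversity``, merged into bp intervals."""
    low = track.values <= max_diversity
    intervals: list[GenomicInterval] = []
    i = 0
    n = len(low)
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1]:
            j += 1
        intervals.append(
            GenomicInterval(track.chrom, int(track.starts[i]), int(track.ends[j]))
        )
        i = j + 1
    return intervals
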