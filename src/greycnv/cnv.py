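"""Diploid copy-number estimation for the tandem CNV.

Two independent assays are modelled:

* read-depth: mean per-window coverage inside the CNV interval, normalised to
  a baseline (a neighbouring CNV-free region), times two;
* droplet digital PCR: Poisson-corrected positive-droplet fractions for a
  target assay inside the duplicated unit and a reference assay at a
  copy-number-stable locus; the concentration ratio times two estimates the
  diploid copy number.

Both return a :class:`CopyNumberCall` with a point estimate, an integer call
(rounding half away from zero) and a 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .model import GenomicInterval

__all__ = [
    "CoverageTrack",
    "DropletAssay",
    "CopyNumberCall",
    "estimate_copy_number_from_coverage",
    "ddpcr_copy_number",
]


def _round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (2.5 -> 3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class CoverageTrack:
    """Mean per-base depth in ordered, non-overlapping fixed-size windows."""

    chrom: str
    starts: np.ndarray  # window start coordinates (bp)
    depths: np.ndarray  # mean per-base depth per window
    window_bp: int

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.starts.shape != self.depths.shape:
            raise ValueError("starts and depths must have equal length")
        if (self.depths < 0).any():
            raise ValueError("window depths must be >= 0")
        if len(self.starts) > 1 and (np.diff(self.starts) < self.window_bp).any():
            raise ValueError("windows must be ordered and non-overlapping")

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window_bp

    def window_mask(self, interval: GenomicInterval) -> np.ndarray:
        """Boolean mask of windows lying entirely inside ``interval``."""
        if interval.chrom != self.chrom:
            return np.zeros(len(self.starts), dtype=bool)
        return (self.starts >= interval.start) & (self.ends <= interval.end)


@dataclass(frozen=True)
class DropletAssay:
    """Positive/total droplet counts for the target and reference channels."""

    target_positive: int
    target_total: int
    reference_positive: int
    reference_total: int

    def __post_init__(self) -> None:
        for pos, tot, name in (
            (self.target_positive, self.target_total, "target"),
            (self.reference_positive, self.reference_total, "reference"),
        ):
            if tot <= 0:
                raise ValueError(f"{name} channel has no droplets")
            if not 0 <= pos <= tot:
                raise ValueError(f"{name} positives outside [0, total]")

    @property
    def saturated_channels(self) -> list[str]:
        out = []
        if self.target_positive == self.target_total:
            out.append("target")
        if self.reference_positive == self.reference_total:
            out.append("reference")
        return out

    @property
    def empty_channels(self) -> list[str]:
        out = []
        if self.target_positive == 0:
            out.append("target")
        if self.reference_positive == 0:
            out.append("reference")
        return out


@dataclass(frozen=True)
class CopyNumberCall:
    """Point estimate of total diploid copies with integer call and 95% CI."""

    estimate: float
    call: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.estimate <= 0:
            raise ValueError("copy-number estimate must be positive")
        if self.call != _round_half_away(self.estimate):
            raise ValueError("integer call must round the point estimate")


def _make_call(estimate: float, ci_low: float, ci_high: float) -> CopyNumberCall:
    return CopyNumberCall(
        estimate=float(estimate),
        call=_round_half_away(estimate),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def estimate_copy_number_from_coverage(
    track: CoverageTrack,
    cnv_interval: GenomicInterval,
    baseline_intervals: Sequence[GenomicInterval] | GenomicInterval,
) -> CopyNumberCall:
    """Estimate diploid copy number as twice the depth ratio CNV/baseline.

    ``baseline_intervals`` plays the role of a control region free of known
    CNVs; its windows must not intersect ``cnv_interval``.
    """
    if isinstance(baseline_intervals, GenomicInterval):
        baseline_intervals = [baseline_intervals]
    for bi in baseline_intervals:
        if bi.overlap(cnv_interval) > 0:
            raise ValueError("baseline intervals must exclude the CNV interval")

    in_cnv = track.window_mask(cnv_interval)
    if not in_cnv.any():
        raise ValueError("no coverage windows inside the CNV interval")
    in_base = np.zeros(len(track.starts), dtype=bool)
    for bi in baseline_intervals:
        in_base |= track.window_mask(bi)
    if not in_base.any():
        raise ValueError("no coverage windows inside the baseline intervals")

    cnv_depths = track.depths[in_cnv]
    base_depths = track.depths[in_base]
    mean_base = base_depths.mean()
    if mean_base <= 0:
        raise ValueError("baseline mean depth is zero")
    mean_cnv = cnv_depths.mean()
    estimate = 2.0 * mean_cnv / mean_base

    # Delta-method CI on the log ratio; with a single window fall back to the
    # Poisson variance of a window mean (depth / window_bp).
    def _rel_var(depths: np.ndarray) -> float:
        n = len(depths)
        m = depths.mean()
        if m <= 0:
            return 0.0
        if n >= 2:
            var_mean = depths.var(ddof=1) / n
        else:
            var_mean = m / track.window_bp
        return var_mean / m**2

    log_sd = math.sqrt(_rel_var(cnv_depths) + _rel_var(base_depths))
    ci_low = estimate * math.exp(-1.959963984540054 * log_sd)
    ci_high = estimate * math.exp(1.959963984540054 * log_sd)
    return _make_call(estimate, ci_low, ci_high)


def ddpcr_copy_number(assay: DropletAssay) -> CopyNumberCall:
    """Poisson-corrected ddPCR copy number.

    Per channel the mean molecules per droplet is ``lambda = -ln(1 - p)`` with
    ``p`` the positive fraction; the diploid copy number is twice the
    target/reference concentration ratio.  The 95% CI propagates the binomial
    standard errors of the positive fractions through the log transform.
    """
    sat = assay.saturated_channels
    if sat:
        raise ValueError(f"saturated ddPCR channel(s): {', '.join(sat)}")
    empty = assay.empty_channels
    if empty:
        raise ValueError(f"empty ddPCR channel(s): {', '.join(empty)}")

    def _lam_and_relvar(pos: int, tot: int) -> tuple[float, float]:
        p = pos / tot
        lam = -math.log1p(-p)
        # Var(lambda-hat) = Var(p-hat) / (1-p)^2 by the delta method.
        var_lam = p * (1 - p) / tot / (1 - p) ** 2
        return lam, var_lam / lam**2

    lam_t, rv_t = _lam_and_relvar(assay.target_positive, assay.target_total)
    lam_r, rv_r = _lam_and_relvar(assay.reference_positive, assay.reference_total)
    estimate = 2.0 * lam_t / lam_r
    log_sd = math.sqrt(rv_t + rv_r)
    ci_low = estimate * math.exp(-1.959963984540054 * log_sd)
    ci_high = estimate * math.exp(1.959963984540054 * log_sd)
    return _make_call(estimate, ci_low, ci_high)
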