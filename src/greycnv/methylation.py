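"""Per-site CpG methylation profiles from long-read calls.

Per-read calls (5mC / 5hmC / unmethylated at known CpG positions on an allele
consensus) are aggregated into per-site methylated fractions, optionally
merging 5mC and 5hmC into a total-methylation fraction.  Profiles are
smoothed in sliding windows of five adjacent CpGs moving one site at a time,
and the hypomethylation of a regulatory subinterval (the MITF-binding
enhancer region of the duplicated unit) is quantified against flanking
sequence as a simple mean contrast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationProfile",
    "HypomethylationContrast",
    "build_methylation_profile",
    "smooth_profile",
    "hypomethylation_contrast",
]

_CALLS = frozenset({"5mC", "5hmC", "unmethylated"})


@dataclass
class MethylationProfile:
    """Ordered CpG positions with per-site methylated fraction and call depth."""

    positions: np.ndarray  # strictly increasing; bp or consensus coordinates
    fractions: np.ndarray  # in [0, 1]
    depths: np.ndarray  # calls per site

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.depths = np.asarray(self.depths)
        if not (len(self.positions) == len(self.fractions) == len(self.depths)):
            raise ValueError("profile arrays must have equal length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")
        if ((self.fractions < 0) | (self.fractions > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pos": self.positions, "fraction": self.fractions, "depth": self.depths}
        )


def build_methylation_profile(
    per_read_calls: pd.DataFrame,
    merge_hydroxymethyl: bool = True,
    known_cpg_positions: Optional[Iterable[int]] = None,
) -> MethylationProfile:
    """Aggregate per-read CpG calls into a per-site profile.

    ``per_read_calls`` needs columns ``read_id, cpg_pos, call`` with calls in
    {5mC, 5hmC, unmethylated}.  The per-site fraction counts 5mC calls, plus
    5hmC calls when ``merge_hydroxymethyl`` (total methylation); sites with
    zero calls are omitted.  When ``known_cpg_positions`` is given, a call at
    any other position raises an error naming the offending position.
    """
    required = {"read_id", "cpg_pos", "call"}
    if not required <= set(per_read_calls.columns):
        raise ValueError(f"calls frame must have columns {sorted(required)}")
    bad_calls = set(per_read_calls["call"]) - _CALLS
    if bad_calls:
        raise ValueError(f"unknown call values: {sorted(bad_calls)}")
    if known_cpg_positions is not None:
        known = set(int(p) for p in known_cpg_positions)
        seen = set(int(p) for p in per_read_calls["cpg_pos"].unique())
        stray = seen - known
        if stray:
            raise ValueError(
                f"call at non-CpG position {sorted(stray)[0]}"
            )
    methylated_calls = {"5mC", "5hmC"} if merge_hydroxymethyl else {"5mC"}
    grouped = per_read_calls.groupby("cpg_pos")["call"]
    depth = grouped.size()
    meth = grouped.apply(lambda s: s.isin(methylated_calls).sum())
    positions = depth.index.to_numpy()
    return MethylationProfile(
        positions=positions,
        fractions=(meth / depth).to_numpy(),
        depths=depth.to_numpy(),
    )


def smooth_profile(
    profile: MethylationProfile,
    window_cpgs: int = 5,
    step_cpgs: int = 1,
) -> MethylationProfile:
    """Sliding-window mean over adjacent CpGs (default 5-site windows moving
    one site at a time).

    Output value i is the mean of sites i..i+window-1; the window position is
    the mean of the member positions and the reported depth the summed call
    depth of the window.
    """
    n = profile.n_sites
    if n < window_cpgs:
        raise ValueError(f"need at least {window_cpgs} CpG sites, got {n}")
    starts = np.arange(0, n - window_cpgs + 1, step_cpgs)
    win = window_cpgs

    csum_frac = np.concatenate([[0.0], np.cumsum(profile.fractions)])
    csum_pos = np.concatenate([[0.0], np.cumsum(profile.positions.astype(float))])
    csum_depth = np.concatenate([[0], np.cumsum(profile.depths)])

    fractions = (csum_frac[starts + win] - csum_frac[starts]) / win
    positions = (csum_pos[starts + win] - csum_pos[starts]) / win
    depths = csum_depth[starts + win] - csum_depth[starts]
    return MethylationProfile(positions=positions, fractions=fractions, depths=depths)


@dataclass(frozen=True)
class HypomethylationContrast:
    mean_target: float
    mean_flank: float

    @property
    def difference(self) -> float:
        """Mean flank fraction minus mean target fraction; positive when the
        target region is hypomethylated relative to its flanks."""
        return self.mean_flank - self.mean_target


def _interval_mask(
    positions: np.ndarray, intervals: Sequence[tuple[int, int]]
) -> np.ndarray:
    mask = np.zeros(len(positions), dtype=bool)
    for start, end in intervals:
        mask |= (positions >= start) & (positions < end)
    return mask


def hypomethylation_contrast(
    profile: MethylationProfile,
    target_intervals: Sequence[tuple[int, int]],
    flank_intervals: Sequence[tuple[int, int]],
) -> HypomethylationContrast:
    """Mean methylated fraction inside target vs flank intervals.

    Intervals are half-open ``(start, end)`` pairs in profile coordinates;
    each set must contain at least one CpG site.
    """
    t_mask = _interval_mask(profile.positions, target_intervals)
    f_mask = _interval_mask(profile.positions, flank_intervals)
    if not t_mask.any():
        raise ValueError("target intervals contain no CpG sites")
    if not f_mask.any():
        raise ValueError("flank intervals contain no CpG sites")
    return HypomethylationContrast(
        mean_target=float(profile.fractions[t_mask].mean()),
        mean_flank=float(profile.fractions[f_mask].mean()),
    )
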