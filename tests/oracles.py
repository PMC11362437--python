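"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (and scipy's test
implementations) they are checking: the Fisher oracle enumerates
hypergeometric tables in exact integer arithmetic, the scan oracle is a
naive double loop, and the flank oracle tries every length explicitly.
"""

from functools import lru_cache
from math import comb

import numpy as np


@lru_cache(maxsize=None)
def _hypergeom_weights(r1: int, c1: int, n: int):
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    return lo, tuple(comb(c1, k) * comb(n - c1, r1 - k) for k in range(lo, hi + 1))


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration of all tables with the observed
    margins, summing those whose point probability is at most the observed
    one (integer-weight comparison, so ties are exact)."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    lo, weights = _hypergeom_weights(r1, c1, n)
    w_obs = weights[a - lo]
    return min(1.0, sum(w for w in weights if w <= w_obs) / comb(n, r1))


def opposite_homozygote_oracle(a, b, window_snps, step_snps):
    """Naive double-loop window fractions over two genotype vectors
    (missing-free)."""
    n = len(a)
    fractions = []
    for start in range(0, n - window_snps + 1, step_snps):
        count = 0
        for i in range(start, start + window_snps):
            if (a[i] == 0 and b[i] == 2) or (a[i] == 2 and b[i] == 0):
                count += 1
        fractions.append(count / window_snps)
    return np.array(fractions)


def longest_common_flank_oracle(upstream: str, downstream: str) -> str:
    """Try every flank length explicitly, longest first."""
    best = ""
    for k in range(1, min(len(upstream), len(downstream)) + 1):
        if upstream[len(upstream) - k :] == downstream[:k]:
            best = downstream[:k]
    return best
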