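"""Independent brute-force oracles used across the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np


def chainable(pairs: list[tuple[int, int]]) -> bool:
    """Can these value pairs be ordered into a componentwise
    non-increasing sequence?  (Sort by (a desc, b desc); the order is then
    forced up to ties, so it suffices to check b.)"""
    srt = sorted(pairs, key=lambda p: (-p[0], -p[1]))
    return all(srt[i][1] >= srt[i + 1][1] for i in range(len(srt) - 1))


def brute_chain(a, b) -> int:
    """Longest dominance chain by exhaustive enumeration of column subsets."""
    a = list(a)
    b = list(b)
    n = len(a)
    best = 0
    for size in range(n, best, -1):
        for sub in combinations(range(n), size):
            if chainable([(a[j], b[j]) for j in sub]):
                return size
    return best


def brute_trend(a, b) -> int:
    """Longest chain over both orientations of b."""
    return max(brute_chain(a, b), brute_chain(a, [-x for x in b]))


def submatrix_is_trend_preserved(sub: np.ndarray) -> bool:
    """Directly check the defining property: every row pair of the integer
    submatrix admits a full-length chain in one of the two orientations."""
    from arbic._kernels import trend_length

    t, s = sub.shape
    for i in range(t):
        for j in range(i + 1, t):
            length, _ = trend_length(sub[i], sub[j])
            if length < s:
                return False
    return True
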