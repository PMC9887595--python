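"""Row partitioning and seed enumeration.

A true bicluster with at least t_min rows spread over k = ⌊t_min/2⌋ random
subsets necessarily places two of its rows in one subset (pigeonhole), so it
suffices to enumerate optimum seeds for within-subset row pairs only —
O(m²/k) seeds instead of O(m²).  t_min is the smallest row count at which a
trend-preserving t×s submatrix is unexpected by chance: the union-bound
expectation C(m,t)·C(n,s)·(2/s!)^t must fall below the significance level
p, with s the smallest seed length considered significant
(max(5, ⌈0.1·n⌉) by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .pdag import Seed
from ._kernels import chain_groups, trend_length
from .matrix_io import Bicluster
from .preprocess import DiscreteMatrix

__all__ = [
    "RowPartition",
    "SeedList",
    "estimate_k",
    "partition_rows",
    "enumerate_seeds",
    "purge_seeds",
]


@dataclass
class RowPartition:
    """Balanced random assignment of rows to k subsets."""

    k: int
    assignment: np.ndarray
    rng_seed: int

    def subsets(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignment == s) for s in range(self.k)]


@dataclass
class _SeedRecord:
    """Lightweight seed handle: the path is rebuilt lazily on pop."""

    row_i: int
    row_j: int
    sign: int
    length: int


class SeedList:
    """Seeds sorted by descending length; ties by (row_i, row_j) ascending."""

    def __init__(self, records: list[_SeedRecord], dmat: DiscreteMatrix):
        self._records = sorted(
            records, key=lambda r: (-r.length, r.row_i, r.row_j)
        )
        self._dmat = dmat

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def peek_length(self) -> int:
        return self._records[0].length if self._records else 0

    def pop(self) -> Seed:
        """Remove and materialize the longest remaining seed."""
        rec = self._records.pop(0)
        lev = self._dmat.levels
        groups = chain_groups(lev[rec.row_i], rec.sign * lev[rec.row_j])
        return Seed(
            sign=rec.sign, groups=groups, row_i=rec.row_i, row_j=rec.row_j
        )


def _log_expected(m: int, n: int, t: int, s: int) -> float:
    """log of the union-bound expected number of chance t×s trend-preserving
    submatrices: C(m,t)·C(n,s)·(2/s!)^t."""

    def logC(a: int, b: int) -> float:
        return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))

    return logC(m, t) + logC(n, s) + t * (np.log(2.0) - float(gammaln(s + 1)))


def estimate_k(m: int, n: int, p_value: float, s_min: int | None = None) -> int:
    """Number of row subsets guaranteeing each true bicluster a seed pair.

    Returns k = max(1, ⌊t_min/2⌋) where t_min is the smallest t ≥ 2 whose
    chance expectation falls below ``p_value``; if no t ≤ m qualifies, t_min
    defaults to m.
    """
    if m < 2 or n < 2:
        raise ValueError("need m >= 2 and n >= 2")
    if not 0 < p_value < 1:
        raise ValueError("p_value must lie in (0, 1)")
    s = s_min if s_min is not None else max(5, int(np.ceil(0.1 * n)))
    s = min(s, n)
    logp = np.log(p_value)
    t_min = m
    for t in range(2, m + 1):
        if _log_expected(m, n, t, s) < logp:
            t_min = t
            break
    return max(1, t_min // 2)


def partition_rows(m: int, k: int, rng_seed: int) -> RowPartition:
    """Uniformly random balanced partition, reproducible from the seed."""
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(m)
    assignment = np.empty(m, dtype=np.int64)
    for s, chunk in enumerate(np.array_split(perm, k)):
        assignment[chunk] = s
    return RowPartition(k=k, assignment=assignment, rng_seed=rng_seed)


def enumerate_seeds(dmat: DiscreteMatrix, partition: RowPartition) -> SeedList:
    """One optimum trend seed per unordered within-subset row pair."""
    lev = dmat.levels
    records: list[_SeedRecord] = []
    for subset in partition.subsets():
        for ii in range(subset.size):
            a = lev[subset[ii]]
            for jj in range(ii + 1, subset.size):
                length, sign = trend_length(a, lev[subset[jj]])
                records.append(
                    _SeedRecord(
                        row_i=int(subset[ii]),
                        row_j=int(subset[jj]),
                        sign=sign,
                        length=length,
                    )
                )
    return SeedList(records, dmat)


def purge_seeds(seeds: SeedList, found: Bicluster) -> SeedList:
    """Drop every seed whose row pair touches ``found``; modifies in place.

    A seed with even one endpoint row inside an already-discovered bicluster
    can only re-extend into (a fragment of) that bicluster — the greedy
    recruitment is pulled back toward the discovered rows — so such seeds
    are discarded along with those fully contained in it.
    """
    rows = set(int(i) for i in found.rows)
    seeds._records = [
        r for r in seeds._records if r.row_i not in rows and r.row_j not in rows
    ]
    return seeds
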