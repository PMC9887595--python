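"""Seed extension: exact greedy core growth, then noise-tolerant relaxation.

The consensus trend of the current bicluster is carried by an auxiliary seed:
an integer vector ranking the columns of the current path (columns of one
contracted clique share a rank, columns off the path carry the sentinel D).
Recruiting a row reduces to the same longest-dominance-chain computation used
for seeding, run on (auxiliary ranks, candidate row); the chain's columns
become the new (possibly narrower) column set.

Internally the consensus groups are kept in an order along which every member
row — after applying its ±1 sign — has non-increasing levels.  The chain
kernel is fed the negated rank vector so chains traverse that stored order
forward, which keeps all row signs directly comparable across iterations.

Core growth maximizes min{|I|, |J|}: the trajectory trades columns for rows,
the best state seen is returned, and growth stops after three consecutive
non-improving recruitments (a pure local-max stop can quit on plateaus).

The noisy stage then adds, in one pass, every outside column whose agreeing
row fraction c_j exceeds α (columns first, judged against the core) and every
outside row whose agreeing column fraction c_i exceeds α (judged against the
column-extended core); α = 0.9 by default and the stage never removes
anything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import chain_groups, trend_length
from .matrix_io import Bicluster
from .pdag import Seed
from .preprocess import DiscreteMatrix

__all__ = ["D", "AuxiliarySeed", "make_auxiliary", "extend_core", "extend_noisy"]

#: sentinel rank for columns excluded from the consensus path
D = 0


@dataclass
class AuxiliarySeed:
    """Rank vector over all n columns: 1..h along the path, D elsewhere."""

    v: np.ndarray
    h: int

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=np.int64)

    @property
    def on_path(self) -> np.ndarray:
        return np.flatnonzero(self.v != D)


def make_auxiliary(groups: list[np.ndarray], n: int) -> AuxiliarySeed:
    """Auxiliary seed for a path given as bloomed clique groups.

    Column j of the i-th group (1-based along the path) gets rank i; columns
    off the path get the sentinel D.
    """
    if not groups:
        raise ValueError("path must be nonempty")
    v = np.full(n, D, dtype=np.int64)
    for i, g in enumerate(groups, start=1):
        if np.any(g >= n):
            raise ValueError("path column index out of range")
        v[g] = i
    return AuxiliarySeed(v=v, h=len(groups))


def _local_ranks(groups: list[np.ndarray], J: np.ndarray) -> np.ndarray:
    """Rank of each column of J (path order), as a local vector aligned to J."""
    pos = {int(c): p for p, c in enumerate(J)}
    vloc = np.empty(J.size, dtype=np.int64)
    for i, g in enumerate(groups, start=1):
        for c in g:
            vloc[pos[int(c)]] = i
    return vloc


def _bicluster_from_state(
    I: list[int],
    signs: list[int],
    groups: list[np.ndarray],
) -> Bicluster:
    rows = np.array(I, dtype=np.int64)
    sgn = np.array(signs, dtype=np.int64)
    order = np.argsort(rows)
    cols = np.sort(np.concatenate(groups))
    return Bicluster(
        rows=rows[order],
        cols=cols,
        signs=sgn[order],
        consensus=[g.copy() for g in groups],
    )


def extend_core(seed: Seed, dmat: DiscreteMatrix) -> Bicluster | None:
    """Grow a seed into a core bicluster by exact greedy row recruitment.

    Returns None when the seed cannot support a bicluster (path shorter
    than 2 columns).
    """
    lev = dmat.levels
    m, _ = lev.shape
    if seed.length < 2 or seed.row_i is None:
        return None
    I: list[int] = [seed.row_i, seed.row_j]
    signs: list[int] = [1, seed.sign]
    groups = [g.copy() for g in seed.groups]

    def key(nI: int, nJ: int) -> tuple[int, int]:
        return (min(nI, nJ), nI * nJ)

    best_state = (list(I), list(signs), [g.copy() for g in groups])
    best_key = key(2, seed.length)
    non_improve = 0

    cache: dict[int, tuple[int, int]] = {}
    cache_tag: bytes | None = None
    while len(I) < m:
        J = np.concatenate(groups)
        vloc = _local_ranks(groups, J)
        avec = -vloc  # chains then traverse the stored order forward
        tag = J.tobytes() + vloc.tobytes()
        if tag != cache_tag:
            in_I = set(I)
            sub = lev[:, J]
            cache = {
                r: trend_length(avec, sub[r]) for r in range(m) if r not in in_I
            }
            cache_tag = tag
        if not cache:
            break
        # argmax by chain length, ties by smaller row index
        best_r = min(cache, key=lambda r: (-cache[r][0], r))
        length_r, sign_r = cache.pop(best_r)
        if length_r < 2:
            break
        loc_groups = chain_groups(avec, sign_r * lev[best_r, J])
        groups = [np.sort(J[g]) for g in loc_groups]
        I.append(best_r)
        signs.append(sign_r)
        k = key(len(I), length_r)
        if k > best_key:
            best_key = k
            best_state = (list(I), list(signs), [g.copy() for g in groups])
            non_improve = 0
        else:
            non_improve += 1
            if non_improve >= 3:
                break
    return _bicluster_from_state(*best_state)


def extend_noisy(core: Bicluster, dmat: DiscreteMatrix, alpha: float = 0.9) -> Bicluster:
    """One-pass α-tolerant extension of a core bicluster.

    Columns outside J are added when the fraction c_j of core rows that stay
    consistent with the consensus after appending the column exceeds α; rows
    outside I are then added when the fraction c_i of (extended) columns at
    which the row follows the consensus trend — best over both orientations —
    exceeds α.  The result always contains the core.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    lev = dmat.levels
    m, n = lev.shape
    if core.consensus is None:
        raise ValueError("core bicluster lacks consensus groups")
    I = core.rows
    signs = core.signs
    groups = [g.copy() for g in core.consensus]
    h = len(groups)
    t = I.size

    # per-row min/max signed level within each consensus group
    signed = signs[:, None] * lev[I]  # (t, n)
    gmin = np.empty((t, h))
    gmax = np.empty((t, h))
    for g, cols in enumerate(groups):
        block = signed[:, cols]
        gmin[:, g] = block.min(axis=1)
        gmax[:, g] = block.max(axis=1)
    # gap g in 0..h inserts between group g and g+1 (1-based groups)
    left = np.hstack([np.full((t, 1), np.inf), gmin])  # upper bound per gap
    right = np.hstack([gmax, np.full((t, 1), -np.inf)])  # lower bound per gap

    # A column agrees with the core when one insertion window fits > α of
    # the rows.  A window spans gaps g..g2 and may skip the consensus
    # columns strictly between them, up to the same disagreement budget
    # rows get, ⌊(1−α)·|J|⌋ columns — otherwise a single spurious consensus
    # column (which can survive the exact stage by chance) would split the
    # feasible gap of a genuinely agreeing column across rows.
    sizes = np.array([g.size for g in groups])
    csum = np.concatenate([[0], np.cumsum(sizes)])  # csum[g] cols before gap g
    tol = int(np.floor((1.0 - alpha) * core.cols.size))
    gg, gg2 = np.meshgrid(np.arange(h + 1), np.arange(h + 1), indexing="ij")
    valid = (gg <= gg2) & ((csum[gg2] - csum[gg]) <= tol)

    in_J = np.zeros(n, dtype=bool)
    in_J[core.cols] = True
    added_cols: list[tuple[int, int, float]] = []  # (gap, col, mean level)
    for j in range(n):
        if in_J[j]:
            continue
        b = signed[:, j]
        le = b[:, None] <= left  # row fits below gap g's upper bound
        ge = b[:, None] >= right  # row fits above gap g2's lower bound
        counts = le.astype(np.int64).T @ ge.astype(np.int64)
        if counts[valid].max() / t > alpha:
            gap = int(np.argmax(np.diagonal(counts)))
            added_cols.append((gap, j, float(b.mean())))

    if added_cols:
        # insert new singleton groups at their gaps; within one gap order by
        # descending mean signed level (approximately monotone), then column
        added_cols.sort(key=lambda x: (x[0], -x[2], x[1]))
        new_groups: list[np.ndarray] = []
        queue = list(added_cols)
        for g in range(h + 1):
            while queue and queue[0][0] == g:
                _, j, _ = queue.pop(0)
                new_groups.append(np.array([j], dtype=np.int64))
            if g < h:
                new_groups.append(groups[g])
        groups = new_groups

    J = np.concatenate(groups)
    vloc = _local_ranks(groups, J)
    avec = -vloc
    in_I = set(int(i) for i in I)
    sub = lev[:, J]
    new_rows: list[int] = []
    new_signs: list[int] = []
    for r in range(m):
        if r in in_I:
            continue
        length, sg = trend_length(avec, sub[r])
        if length / J.size > alpha:
            new_rows.append(r)
            new_signs.append(sg)

    rows = np.concatenate([I, np.array(new_rows, dtype=np.int64)])
    all_signs = np.concatenate([signs, np.array(new_signs, dtype=np.int64)])
    order = np.argsort(rows)
    return Bicluster(
        rows=rows[order],
        cols=np.sort(J),
        score=core.score,
        signs=all_signs[order],
        consensus=groups,
    )
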