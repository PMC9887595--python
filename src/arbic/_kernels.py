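"""Longest weighted dominance-chain kernels.

For a pair of integer vectors (a, b) over the same columns, a dominance chain
is a sequence of columns along which the value pairs (a_j, b_j) are
componentwise non-increasing.  Columns with identical value pairs form a
clique that is contracted to a single weighted vertex; the longest weighted
path through the contracted DAG (weight = clique size) equals the longest
chain through the original columns.

The DP runs over the unique value pairs sorted by (a desc, b desc) — a
topological order of the contracted DAG — and is O(u^2) in the number u of
unique pairs.  Tie-breaks are fixed so results are fully deterministic:

* among equal-score predecessors the earliest vertex in the sorted order wins;
* among equal-score chain ends the earliest vertex in the sorted order wins;
* clique members are bloomed in ascending column order.

When numba is importable the inner loop is JIT-compiled; otherwise a
pure-NumPy row-sweep with identical tie-breaking is used.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _dp(a: np.ndarray, b: np.ndarray, w: np.ndarray):
    """DP over unique pairs sorted by (a desc, b desc).

    Returns (best, parent): best[i] = max total weight of a chain ending at
    vertex i, parent[i] = predecessor index or -1.
    """
    u = a.shape[0]
    best = np.empty(u, np.int64)
    parent = np.full(u, -1, np.int64)
    for i in range(u):
        bi = b[i]
        acc = 0
        arg = -1
        for j in range(i):
            # a[j] >= a[i] holds by sort order; edge j -> i iff b[j] >= b[i]
            if b[j] >= bi and best[j] > acc:
                acc = best[j]
                arg = j
        best[i] = acc + w[i]
        parent[i] = arg
    return best, parent


def _dp_py(a: np.ndarray, b: np.ndarray, w: np.ndarray):
    u = a.shape[0]
    best = np.empty(u, np.int64)
    parent = np.full(u, -1, np.int64)
    for i in range(u):
        ok = np.flatnonzero(b[:i] >= b[i])
        if ok.size:
            prev = best[ok]
            k = int(np.argmax(prev))  # first maximum -> earliest vertex
            best[i] = prev[k] + w[i]
            parent[i] = ok[k]
        else:
            best[i] = w[i]
    return best, parent


if not _HAVE_NUMBA:  # pragma: no cover
    _dp = _dp_py


def _group(a: np.ndarray, b: np.ndarray):
    """Sort columns by (a desc, b desc) and contract equal value pairs.

    Returns (order, starts, ua, ub, w) where `order` is the column
    permutation, `starts` the first index of each unique pair within it,
    `ua`/`ub` the unique pair values and `w` the clique sizes.
    """
    order = np.lexsort((-b, -a))
    a_s = a[order]
    b_s = b[order]
    n = a_s.shape[0]
    flags = np.empty(n, dtype=bool)
    flags[0] = True
    np.logical_or(a_s[1:] != a_s[:-1], b_s[1:] != b_s[:-1], out=flags[1:])
    starts = np.flatnonzero(flags)
    w = np.diff(np.append(starts, n))
    return order, starts, a_s[starts], b_s[starts], w


def chain_length(a: np.ndarray, b: np.ndarray) -> int:
    """Length (number of columns) of the longest dominance chain of (a, b)."""
    if a.shape[0] == 0:
        return 0
    _, _, ua, ub, w = _group(np.ascontiguousarray(a), np.ascontiguousarray(b))
    best, _ = _dp(ua, ub, w.astype(np.int64))
    return int(best.max())


def chain_groups(a: np.ndarray, b: np.ndarray) -> list[np.ndarray]:
    """Longest dominance chain of (a, b) as bloomed clique groups.

    Groups are returned in path order (value pairs non-increasing); members
    of each group are sorted ascending by column index.
    """
    if a.shape[0] == 0:
        return []
    order, starts, ua, ub, w = _group(
        np.ascontiguousarray(a), np.ascontiguousarray(b)
    )
    best, parent = _dp(ua, ub, w.astype(np.int64))
    end = int(np.argmax(best))  # first maximum -> earliest vertex
    rev = []
    v = end
    while v >= 0:
        rev.append(v)
        v = int(parent[v])
    rev.reverse()
    n = a.shape[0]
    bounds = np.append(starts, n)
    return [np.sort(order[bounds[g] : bounds[g + 1]]) for g in rev]


def trend_length(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Best chain length over both orientations of ``b``.

    Returns (length, sign); ties prefer sign +1.
    """
    l_pos = chain_length(a, b)
    l_neg = chain_length(a, -b)
    if l_neg > l_pos:
        return l_neg, -1
    return l_pos, 1
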