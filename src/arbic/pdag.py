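"""Pseudo-DAG seed optimization for a pair of integer rows.

For rows a, b over columns 0..n−1 the pseudo-DAG has a directed edge
(s, t) exactly when (a_s, b_s) ≥ (a_t, b_t) componentwise.  An edge is
bidirected iff the value pairs are equal; the subgraph induced by bidirected
edges decomposes into cliques, and contracting each clique (vertex weight =
clique size) yields an acyclic graph whose longest weighted path, bloomed
back to columns, is the optimum 2×L seed for the row pair.

Trend-preservation (order-preserved OR order-reversed) is realized by
running the same machinery on (a, b) and (a, −b) and keeping the longer
result; ties prefer the order-preserved orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._kernels import chain_groups, chain_length

__all__ = [
    "PDAG",
    "ContractedDAG",
    "Seed",
    "build_pdag",
    "contract",
    "longest_seed",
    "longest_seed_trend",
]


@dataclass
class PDAG:
    """Dominance graph of a row pair; edges are implied by the value pairs."""

    row_a: np.ndarray
    row_b: np.ndarray

    @property
    def n(self) -> int:
        return int(self.row_a.size)

    def has_edge(self, s: int, t: int) -> bool:
        return (
            s != t
            and self.row_a[s] >= self.row_a[t]
            and self.row_b[s] >= self.row_b[t]
        )

    def edges(self) -> list[tuple[int, int]]:
        """Explicit edge list (quadratic; intended for small inputs/tests)."""
        n = self.n
        return [
            (s, t) for s in range(n) for t in range(n) if self.has_edge(s, t)
        ]


@dataclass
class ContractedDAG:
    """Clique-contracted pseudo-DAG: weighted supervertices, acyclic."""

    groups: list[np.ndarray]  # column members per supervertex, ascending
    pairs: np.ndarray  # (h, 2) value pair per supervertex
    graph: nx.DiGraph = field(repr=False)

    @property
    def weights(self) -> np.ndarray:
        return np.array([g.size for g in self.groups])


@dataclass
class Seed:
    """Optimum 2×L submatrix of a row pair: an ordered column path.

    ``groups`` lists the bloomed cliques in path order (value pairs
    non-increasing after sign application); ``path`` is the flattened column
    sequence, cliques emitted in ascending column order.
    """

    sign: int
    groups: list[np.ndarray]
    row_i: int | None = None
    row_j: int | None = None

    @property
    def path(self) -> np.ndarray:
        if not self.groups:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(self.groups)

    @property
    def length(self) -> int:
        return int(sum(g.size for g in self.groups))


def _as_rows(row_a, row_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(row_a, dtype=np.int64)
    b = np.asarray(row_b, dtype=np.int64)
    if a.shape != b.shape:
        raise ValueError("row length mismatch")
    if a.size < 2:
        raise ValueError("rows must have length >= 2")
    return a, b


def build_pdag(row_a, row_b) -> PDAG:
    """Dominance pseudo-DAG of a pair of integer rows."""
    a, b = _as_rows(row_a, row_b)
    return PDAG(a, b)


def contract(pdag: PDAG) -> ContractedDAG:
    """Group columns with identical value pairs and contract them.

    The contracted graph keeps one directed edge per dominating supervertex
    pair; since all value pairs are distinct after contraction it is acyclic.
    """
    a, b = pdag.row_a, pdag.row_b
    order = np.lexsort((-b, -a))
    a_s, b_s = a[order], b[order]
    flags = np.ones(a_s.size, dtype=bool)
    flags[1:] = (a_s[1:] != a_s[:-1]) | (b_s[1:] != b_s[:-1])
    starts = np.flatnonzero(flags)
    bounds = np.append(starts, a_s.size)
    groups = [
        np.sort(order[bounds[i] : bounds[i + 1]]) for i in range(starts.size)
    ]
    pairs = np.column_stack((a_s[starts], b_s[starts]))
    g = nx.DiGraph()
    h = len(groups)
    for i in range(h):
        g.add_node(i, weight=int(groups[i].size))
    for i in range(h):
        for j in range(h):
            if i != j and pairs[i, 0] >= pairs[j, 0] and pairs[i, 1] >= pairs[j, 1]:
                g.add_edge(i, j)
    return ContractedDAG(groups=groups, pairs=pairs, graph=g)


def longest_seed(row_a, row_b) -> Seed:
    """Longest weighted dominance path of (row_a, row_b), bloomed to columns."""
    a, b = _as_rows(row_a, row_b)
    return Seed(sign=1, groups=chain_groups(a, b))


def longest_seed_trend(row_a, row_b) -> Seed:
    """Best seed over both orientations of row_b; ties prefer sign +1."""
    a, b = _as_rows(row_a, row_b)
    l_pos = chain_length(a, b)
    l_neg = chain_length(a, -b)
    if l_neg > l_pos:
        return Seed(sign=-1, groups=chain_groups(a, -b))
    return Seed(sign=1, groups=chain_groups(a, b))
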