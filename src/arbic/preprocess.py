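"""Qualitative (integer) representation of an expression matrix.

Each row is discretized independently of its magnitudes — only within-row
ranks matter — into integer levels −r..r:

* the whole row is banded equal-frequency into 2r+1 levels using mid-rank
  fractions, so the median band maps to 0 and a constant row maps to an
  all-zero row;
* the extreme levels ±r are additionally capped to the ⌈q·n⌉ most extreme
  entries per tail (entries beyond that cap are clamped to ±(r−1)), so q
  keeps its QUBIC-family meaning of "fraction of a row treated as strongly
  up/down regulated".

With r = 1 this reduces to the classic up/flat/down representation (exactly
⌈q·n⌉ entries at +1 and −1, ties permitting).  The default r = 15 keeps
fine-grained ordering information, which the dominance-chain seeding needs;
equal input values always receive equal levels so that equal value pairs
contract into cliques downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix_io import ExpressionMatrix

__all__ = ["DiscreteMatrix", "discretize"]


@dataclass
class DiscreteMatrix:
    """Integer qualitative matrix with entries in {−r..r}."""

    levels: np.ndarray
    r: int
    q: float

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


def _discretize_row(row: np.ndarray, q: float, r: int) -> np.ndarray:
    n = row.size
    # mid-rank fraction per entry: ties share the mean rank of their run
    sorted_vals = np.sort(row)
    # first and last occurrence rank of each value
    uniq, first = np.unique(sorted_vals, return_index=True)
    last = np.append(first[1:], n) - 1
    mid = (first + last) / 2.0 + 0.5  # in (0, n)
    frac = mid[np.searchsorted(uniq, row)] / n
    lev = np.floor(frac * (2 * r + 1)).astype(np.int64) - r
    np.clip(lev, -r, r, out=lev)

    # cap the extreme levels to the ceil(q*n) most extreme entries (tie-safe:
    # entries tied with the cut are excluded, so the cap is never exceeded)
    s_tail = int(np.ceil(q * n))
    if q * n < 1:
        warnings.warn(
            "q*n < 1: regulated tails have size 1", RuntimeWarning, stacklevel=3
        )
    hi_cut = sorted_vals[n - s_tail - 1] if s_tail < n else -np.inf
    lo_cut = sorted_vals[s_tail] if s_tail < n else np.inf
    lev[(lev == r) & (row <= hi_cut)] = r - 1
    lev[(lev == -r) & (row >= lo_cut)] = -(r - 1)
    return lev


def discretize(matrix: ExpressionMatrix, q: float = 0.06, r: int = 15) -> DiscreteMatrix:
    """Row-wise rank discretization into levels −r..r.

    Parameters
    ----------
    matrix : ExpressionMatrix
    q : quantile parameter in (0, 0.5) capping the ±r extremes per row.
    r : number of positive (and negative) levels, r ≥ 1.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    if r < 1:
        raise ValueError("r must be >= 1")
    vals = matrix.values
    levels = np.empty(vals.shape, dtype=np.int64)
    for i in range(vals.shape[0]):
        row = vals[i]
        if np.all(row == row[0]):
            levels[i] = 0  # degenerate constant row
            continue
        levels[i] = _discretize_row(row, q, r)
    return DiscreteMatrix(levels, r=r, q=q)
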