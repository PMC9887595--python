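"""Bicluster significance score (BS) and output ranking.

For a t×s trend-preserving bicluster in an m×n matrix the chance probability
of the pattern is (2/s!)^t; the score

    BS = −log((2·n·m·t / s!)^t) = −t·(log(2nmt) − log s!)

rewards both more rows and (strongly) more columns.  Logs are natural and
log s! is evaluated via the log-gamma function so arbitrary s cannot
overflow.  A "text" variant without the inner factor t is also available;
both are monotone the same way so rankings rarely differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .evaluate import match_score
from .matrix_io import Bicluster

__all__ = ["ScoreParams", "bs_score", "rank_and_select"]


@dataclass
class ScoreParams:
    """Data-matrix dimensions entering the BS score."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m < 2 or self.n < 2:
            raise ValueError("need m >= 2 and n >= 2")


def bs_score(
    t: int, s: int, params: ScoreParams, variant: str = "display"
) -> float:
    """Significance score of a t×s bicluster; larger is more significant.

    ``variant="display"`` uses (2nmt/s!)^t, ``variant="text"`` uses
    (2nm/s!)^t.
    """
    if t < 2 or s < 2:
        raise ValueError("need t >= 2 and s >= 2")
    if variant == "display":
        inner = np.log(2.0 * params.n * params.m * t)
    elif variant == "text":
        inner = np.log(2.0 * params.n * params.m)
    else:
        raise ValueError(f"unknown score variant {variant!r}")
    return float(-t * (inner - gammaln(s + 1)))


def _containment(b1: Bicluster, b2: Bicluster) -> float:
    """Fraction of the smaller bicluster's cells shared with the other."""
    ri = np.intersect1d(b1.rows, b2.rows, assume_unique=True).size
    ci = np.intersect1d(b1.cols, b2.cols, assume_unique=True).size
    return (ri * ci) / min(b1.n_rows * b1.n_cols, b2.n_rows * b2.n_cols)


def rank_and_select(
    biclusters: list[Bicluster],
    o: int,
    min_score: float | None = None,
    overlap_threshold: float = 0.9,
    containment_threshold: float = 0.5,
) -> list[Bicluster]:
    """Top-o biclusters by descending BS, redundancy suppressed.

    Candidates are visited in descending score order (ties by discovery
    order).  A candidate is dropped when its element-wise match score with
    an already kept bicluster exceeds ``overlap_threshold`` (a near
    duplicate), or when the majority of its cells are already explained by a
    kept bicluster (containment — the fraction of the smaller block's cells
    shared with the kept one — above ``containment_threshold``; fragments of
    an already reported bicluster add no information).  Candidates scoring
    at or below ``min_score`` are dropped too (None disables that filter).
    """
    if o < 1:
        raise ValueError("o must be >= 1")
    idx = sorted(
        range(len(biclusters)),
        key=lambda i: (
            -(biclusters[i].score if biclusters[i].score is not None else -np.inf),
            i,
        ),
    )
    kept: list[Bicluster] = []
    for i in idx:
        b = biclusters[i]
        if min_score is not None and (b.score is None or b.score <= min_score):
            continue
        if any(
            match_score(b, k) > overlap_threshold
            or _containment(b, k) > containment_threshold
            for k in kept
        ):
            continue
        kept.append(b)
        if len(kept) == o:
            break
    return kept
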