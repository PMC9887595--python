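"""Recovery/relevance evaluation of predicted biclusters against truth.

The element-wise match score of two biclusters is the Jaccard coefficient of
their cell sets (cells are (row, column) pairs of I×J).  For bicluster sets,
s(M1, M2) averages, over M1, each bicluster's best match in M2; with truth T
and predictions P, recovery = s(T, P) and relevance = s(P, T).
"""

from __future__ import annotations

import numpy as np

from .matrix_io import Bicluster

__all__ = [
    "match_score",
    "set_score",
    "recovery_relevance",
    "f1_harmonic",
]


def match_score(b1: Bicluster, b2: Bicluster) -> float:
    """Element-wise Jaccard coefficient of two biclusters, in [0, 1]."""
    ri = np.intersect1d(b1.rows, b2.rows, assume_unique=True).size
    ci = np.intersect1d(b1.cols, b2.cols, assume_unique=True).size
    inter = ri * ci
    union = b1.n_rows * b1.n_cols + b2.n_rows * b2.n_cols - inter
    return inter / union


def set_score(M1: list[Bicluster], M2: list[Bicluster]) -> float:
    """Average over M1 of the best element-wise match in M2 (0 if M2 empty)."""
    if not M1:
        raise ValueError("M1 must be non-empty")
    if not M2:
        return 0.0
    return float(
        np.mean([max(match_score(b1, b2) for b2 in M2) for b1 in M1])
    )


def recovery_relevance(truth, predicted: list[Bicluster]) -> tuple[float, float]:
    """(recovery, relevance) = (s(T, P), s(P, T)); relevance is 0 when
    nothing was predicted.

    ``truth`` may be a list of biclusters or any object exposing a
    ``biclusters`` attribute (e.g. a simulation ground truth).
    """
    T = list(getattr(truth, "biclusters", truth))
    recovery = set_score(T, predicted)
    relevance = set_score(predicted, T) if predicted else 0.0
    return recovery, relevance


def f1_harmonic(F: float, G: float) -> float:
    """Harmonic mean 2FG/(F+G); returns 0 when both inputs are 0."""
    if F < 0 or G < 0:
        raise ValueError("scores must be non-negative")
    if F == 0 and G == 0:
        return 0.0
    return 2.0 * F * G / (F + G)
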