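"""Synthetic expression matrices with implanted pattern biclusters.

The background is an iid N(0,1) matrix (600×600 by default) in which a
configurable fraction of each row's entries is duplicated from other entries
of the same row, mimicking tied expression values.  Implanted submatrices
are then rearranged — each row's own values are re-ordered to follow the
rank order of one fixed row — so every implant is exactly trend-preserving;
shift / scale / shift+scale / row-constant / column-constant / constant
patterns are constructed directly from a shared base profile.

Consecutive implants may overlap in a rows×cols region whose entries are set
to a single constant.  For the overlapping implants to stay trend-preserving
the tied constant block must occupy the same rank interval in every row of
each implant, which is only generally feasible at the extremes of the trend:
region constants are therefore placed just beyond the implants' value range
(alternating above/below for consecutive regions, offset magnitude drawn
from the seeded RNG), and each implant orders its region block at the
corresponding end of its trend.

Row-wise noise replaces ⌊level·s⌋ entries per implant row with fresh N(0,1)
draws, so the measured per-row noise level (fraction of entries whose
removal restores the row's agreement with the consensus) never exceeds the
requested level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import Bicluster, ExpressionMatrix

__all__ = [
    "ImplantSpec",
    "SimulationSpec",
    "GroundTruth",
    "generate",
    "inject_noise",
    "spec_from_yaml",
]

_PATTERNS = {
    "trend",
    "shift",
    "scale",
    "shift+scale",
    "row-constant",
    "column-constant",
    "constant",
}


@dataclass
class ImplantSpec:
    """One implanted bicluster: shape, pattern and row-wise noise level."""

    t: int
    s: int
    pattern: str = "trend"
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.pattern not in _PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not 0 <= self.noise < 1:
            raise ValueError("noise level must lie in [0, 1)")
        if self.t < 2 or self.s < 2:
            raise ValueError("implants must be at least 2x2")


@dataclass
class SimulationSpec:
    """Full description of one synthetic dataset."""

    m: int = 600
    n: int = 600
    implants: list[ImplantSpec] = field(default_factory=list)
    overlap: tuple[int, int] | None = None  # (rows, cols) shared by neighbors
    rng_seed: int = 1
    ties: float = 0.05  # fraction of within-row duplicated values


@dataclass
class GroundTruth:
    """Implanted bicluster index sets, aligned one-to-one with the implants."""

    biclusters: list[Bicluster]


def _placements(spec: SimulationSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    ov_r, ov_c = spec.overlap if spec.overlap is not None else (0, 0)
    out = []
    r0 = c0 = 0
    for idx, imp in enumerate(spec.implants):
        if idx > 0:
            r0 -= ov_r
            c0 -= ov_c
        rows = np.arange(r0, r0 + imp.t)
        cols = np.arange(c0, c0 + imp.s)
        if rows[-1] >= spec.m or cols[-1] >= spec.n:
            raise ValueError("implants do not fit inside the matrix")
        if idx > 0 and (2 * ov_r > imp.t or 2 * ov_c > imp.s):
            raise ValueError("overlap exceeds half an implant; infeasible")
        out.append((rows, cols))
        r0 = rows[-1] + 1
        c0 = cols[-1] + 1
    return out


def inject_noise(block: np.ndarray, level: float, rng: np.random.Generator) -> np.ndarray:
    """Replace ⌊level·s⌋ randomly chosen entries per row with N(0,1) draws."""
    if not 0 <= level < 1:
        raise ValueError("noise level must lie in [0, 1)")
    out = np.array(block, dtype=float, copy=True)
    t, s = out.shape
    k = int(np.floor(level * s))
    if k == 0:
        return out
    for i in range(t):
        pos = rng.choice(s, size=k, replace=False)
        out[i, pos] = rng.standard_normal(k)
    return out


def _arrange_trend(
    A: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    low_cols: np.ndarray,
    high_cols: np.ndarray,
    low_rows: set[int],
    high_rows: set[int],
    c_low: float,
    c_high: float,
) -> None:
    """Rearrange A[rows, cols] into a trend-preserving block in place.

    ``low_cols``/``high_cols`` are overlap-region columns pinned to the
    bottom/top of the trend; rows listed in ``low_rows``/``high_rows`` carry
    the corresponding region constant there.
    """
    low_set = set(int(c) for c in low_cols)
    high_set = set(int(c) for c in high_cols)
    mid_cols = np.array(
        [c for c in cols if int(c) not in low_set and int(c) not in high_set],
        dtype=np.int64,
    )
    # the trend of the fixed (first) row orders the middle columns
    fixed = rows[0]
    mid_order = mid_cols[np.argsort(A[fixed, mid_cols], kind="stable")]
    rank_order = np.concatenate(
        [np.sort(low_cols), mid_order, np.sort(high_cols)]
    ).astype(np.int64)
    for i in rows:
        if int(i) in low_rows:
            own = np.array([c for c in rank_order if int(c) not in low_set])
            vals = np.sort(A[i, own])
            A[i, own] = vals
            A[i, np.sort(low_cols)] = c_low
        elif int(i) in high_rows:
            own = np.array([c for c in rank_order if int(c) not in high_set])
            vals = np.sort(A[i, own])
            A[i, own] = vals
            A[i, np.sort(high_cols)] = c_high
        else:
            vals = np.sort(A[i, rank_order])
            A[i, rank_order] = vals


def _construct_pattern(
    A: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    pattern: str,
    rng: np.random.Generator,
) -> None:
    t, s = rows.size, cols.size
    base = rng.standard_normal(s)
    if pattern == "shift":
        delta = rng.standard_normal(t)
        A[np.ix_(rows, cols)] = base[None, :] + delta[:, None]
    elif pattern == "scale":
        gamma = np.exp(rng.normal(0.0, 0.5, size=t))
        A[np.ix_(rows, cols)] = gamma[:, None] * base[None, :]
    elif pattern == "shift+scale":
        gamma = np.exp(rng.normal(0.0, 0.5, size=t))
        delta = rng.standard_normal(t)
        A[np.ix_(rows, cols)] = gamma[:, None] * base[None, :] + delta[:, None]
    elif pattern == "row-constant":
        A[np.ix_(rows, cols)] = rng.standard_normal(t)[:, None]
    elif pattern == "column-constant":
        A[np.ix_(rows, cols)] = base[None, :]
    elif pattern == "constant":
        A[np.ix_(rows, cols)] = rng.standard_normal()


def generate(spec: SimulationSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Build the synthetic matrix and its ground truth; bit-reproducible."""
    rng = np.random.default_rng(spec.rng_seed)
    m, n = spec.m, spec.n
    A = rng.standard_normal((m, n))

    # within-row ties: duplicate a fraction of each row's values
    k_ties = int(np.floor(spec.ties * n))
    if k_ties > 0:
        for i in range(m):
            dst = rng.choice(n, size=k_ties, replace=False)
            src = rng.integers(0, n, size=k_ties)
            A[i, dst] = A[i, src]

    places = _placements(spec)
    ov_r, ov_c = spec.overlap if spec.overlap is not None else (0, 0)
    has_overlap = ov_r > 0 and ov_c > 0

    # overlap-region constants sit beyond the implant value range, alternating
    # above/below for consecutive regions so each implant pins at most one
    # region per end of its trend
    region_const: list[float] = []
    if has_overlap:
        lo = min(A[np.ix_(r, c)].min() for r, c in places)
        hi = max(A[np.ix_(r, c)].max() for r, c in places)
        for p in range(len(places) - 1):
            off = 0.5 + 0.25 * abs(rng.standard_normal())
            region_const.append(hi + off if p % 2 == 0 else lo - off)

    for idx, (rows, cols) in enumerate(places):
        imp = spec.implants[idx]
        if imp.pattern != "trend":
            if has_overlap:
                raise ValueError(
                    "overlap designs are only defined for trend implants"
                )
            _construct_pattern(A, rows, cols, imp.pattern, rng)
        else:
            low_cols = np.empty(0, dtype=np.int64)
            high_cols = np.empty(0, dtype=np.int64)
            low_rows: set[int] = set()
            high_rows: set[int] = set()
            c_low = c_high = 0.0
            if has_overlap:
                if idx > 0:  # region shared with the previous implant
                    const = region_const[idx - 1]
                    r_shared = rows[:ov_r]
                    c_shared = cols[:ov_c]
                    if (idx - 1) % 2 == 0:
                        high_cols = c_shared
                        high_rows |= set(int(x) for x in r_shared)
                        c_high = const
                    else:
                        low_cols = c_shared
                        low_rows |= set(int(x) for x in r_shared)
                        c_low = const
                if idx < len(places) - 1:  # region shared with the next one
                    const = region_const[idx]
                    r_shared = rows[-ov_r:]
                    c_shared = cols[-ov_c:]
                    if idx % 2 == 0:
                        high_cols = c_shared
                        high_rows |= set(int(x) for x in r_shared)
                        c_high = const
                    else:
                        low_cols = c_shared
                        low_rows |= set(int(x) for x in r_shared)
                        c_low = const
            _arrange_trend(
                A,
                rows,
                cols,
                rng,
                low_cols,
                high_cols,
                low_rows,
                high_rows,
                c_low,
                c_high,
            )
        if imp.noise > 0:
            A[np.ix_(rows, cols)] = inject_noise(
                A[np.ix_(rows, cols)], imp.noise, rng
            )

    matrix = ExpressionMatrix(
        A,
        gene_ids=[f"g{i}" for i in range(m)],
        condition_ids=[f"c{j}" for j in range(n)],
    )
    truth = GroundTruth(
        biclusters=[Bicluster(rows=r, cols=c) for r, c in places]
    )
    return matrix, truth


def spec_from_yaml(path) -> SimulationSpec:
    """Load a SimulationSpec from a YAML file."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    implants = [ImplantSpec(**imp) for imp in doc.get("implants", [])]
    overlap = doc.get("overlap")
    return SimulationSpec(
        m=int(doc.get("m", 600)),
        n=int(doc.get("n", 600)),
        implants=implants,
        overlap=tuple(overlap) if overlap else None,
        rng_seed=int(doc.get("rng_seed", 1)),
        ties=float(doc.get("ties", 0.05)),
    )
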