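"""Simulation study protocols: trend, overlap and noise designs.

Two scales are provided.  The full-scale designs mirror the original
simulation experiments (600×600 background, six 100×100 implants for the
trend and overlap studies, three implants for the noise study, overlap
levels 0/30/40/50).  The desk-scale designs shrink everything by the same
factor (300×300 background, three 60×60 implants, overlaps scaled by the
implant-size ratio 0.6 to 0/18/24/30) so a complete study runs in minutes
on one CPU; docs/methods.md discusses what the reduction preserves.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cli import run_arbic
from .evaluate import recovery_relevance
from .simulate import ImplantSpec, SimulationSpec, generate

__all__ = [
    "StudyResult",
    "trend_spec",
    "overlap_spec",
    "noise_spec",
    "run_study",
    "DESK",
    "FULL",
]


@dataclass
class Scale:
    m: int
    n: int
    n_implants_trend: int
    n_implants_noise: int
    implant: int
    overlaps: tuple[int, ...]


DESK = Scale(
    m=300, n=300, n_implants_trend=3, n_implants_noise=3, implant=60,
    overlaps=(0, 18, 24, 30),
)
FULL = Scale(
    m=600, n=600, n_implants_trend=6, n_implants_noise=3, implant=100,
    overlaps=(0, 30, 40, 50),
)


@dataclass
class StudyResult:
    recovery: float
    relevance: float
    n_predicted: int

    @property
    def mean(self) -> float:
        return 0.5 * (self.recovery + self.relevance)


def trend_spec(scale: Scale, rng_seed: int, noise: float = 0.0) -> SimulationSpec:
    """Disjoint trend-preserving implants (the baseline design)."""
    k = scale.n_implants_trend if noise == 0.0 else scale.n_implants_noise
    return SimulationSpec(
        m=scale.m,
        n=scale.n,
        implants=[
            ImplantSpec(t=scale.implant, s=scale.implant, noise=noise)
            for _ in range(k)
        ],
        rng_seed=rng_seed,
    )


def overlap_spec(scale: Scale, level: int, rng_seed: int) -> SimulationSpec:
    """Trend implants where consecutive implants share a constant
    level×level region."""
    return SimulationSpec(
        m=scale.m,
        n=scale.n,
        implants=[
            ImplantSpec(t=scale.implant, s=scale.implant)
            for _ in range(scale.n_implants_trend)
        ],
        overlap=(level, level) if level > 0 else None,
        rng_seed=rng_seed,
    )


def noise_spec(scale: Scale, level: float, rng_seed: int) -> SimulationSpec:
    """Three disjoint trend implants at a common row-noise level."""
    return SimulationSpec(
        m=scale.m,
        n=scale.n,
        implants=[
            ImplantSpec(t=scale.implant, s=scale.implant, noise=level)
            for _ in range(scale.n_implants_noise)
        ],
        rng_seed=rng_seed,
    )


def run_study(spec: SimulationSpec, pipeline_seed: int = 1, **kwargs) -> StudyResult:
    """Generate a dataset, run the pipeline and score it against truth."""
    import warnings

    matrix, truth = generate(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        predicted = run_arbic(matrix, rng_seed=pipeline_seed, **kwargs)
    recovery, relevance = recovery_relevance(truth, predicted)
    return StudyResult(
        recovery=recovery, relevance=relevance, n_predicted=len(predicted)
    )
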