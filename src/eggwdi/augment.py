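"""Per-timepoint summaries and Monte Carlo "virtual animal" augmentation.

Regulatory tolerance-limit software expects a minimum number of residue
values per timepoint (10 for the US method). A sparse pilot flock rarely
meets that, so each retained timepoint is topped up with draws from a
normal distribution matched to the observed mean and SD at that timepoint,
truncated at the LOD by rejection sampling — sub-LOD values would be
excluded downstream anyway, so the truncation implements that exclusion at
source. Observed values pass through augmentation unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .data import BlqPolicy, Censor, FlockDataset, Matrix, apply_blq_policy

__all__ = [
    "TimepointSummary",
    "AugmentedTimepoint",
    "summarize_timepoints",
    "elimination_phase",
    "augment",
]

DEFAULT_MIN_N = 5
DEFAULT_TARGET_N = 10


class AugmentationError(ValueError):
    """Timepoint data unusable for augmentation."""


@dataclass(frozen=True)
class TimepointSummary:
    """Observed yolk values in one integer-day bin since the final dose."""

    time: float  # days since final dose
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("timepoint needs >= 1 observed value")

    @property
    def n_observed(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if len(self.values) < 2:
            return 0.0
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class AugmentedTimepoint:
    """One timepoint after Monte Carlo top-up to the target sample size."""

    time: float
    observed: tuple[float, ...]
    simulated: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.observed) + len(self.simulated)

    @property
    def values(self) -> tuple[float, ...]:
        return self.observed + self.simulated


def summarize_timepoints(
    data: FlockDataset,
    matrix: Matrix = Matrix.YOLK,
    min_n: int = DEFAULT_MIN_N,
) -> list[TimepointSummary]:
    """Bin non-censored observations to integer days since the final dose
    and keep bins with at least ``min_n`` values.

    The below-LOD exclusion policy is applied here regardless of upstream
    filtering (idempotent), so means and SDs are statistics of detectable
    residues only. Bins are returned in time order.
    """
    filtered = apply_blq_policy(data, BlqPolicy.EXCLUDE_BELOW_LOD)
    bins: dict[int, list[float]] = {}
    for obs in filtered.observations:
        if obs.matrix is not matrix or obs.concentration is None:
            continue
        if obs.time < 0:
            continue  # depletion methods use post-final-dose data only
        bins.setdefault(int(round(obs.time)), []).append(obs.concentration)
    out = [
        TimepointSummary(float(day), tuple(vals))
        for day, vals in sorted(bins.items())
        if len(vals) >= min_n
    ]
    if not out:
        raise AugmentationError(
            f"no timepoint has >= {min_n} detectable {matrix.value} values"
        )
    return out


def elimination_phase(summaries: Sequence[TimepointSummary]) -> list[TimepointSummary]:
    """Timepoints strictly after the peak of the per-timepoint means.

    Depletion regressions assume a declining phase; bins up to and including
    the maximum-mean bin belong to the absorption/peak region and are
    dropped.
    """
    if not summaries:
        return []
    means = [s.mean for s in summaries]
    peak = int(np.argmax(means))
    return list(summaries[peak + 1:])


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, lod: float, k: int
) -> np.ndarray:
    """k draws from Normal(mean, sd) truncated below at lod, by rejection."""
    if sd == 0.0:
        return np.full(k, mean)
    out = np.empty(0)
    while len(out) < k:
        cand = rng.normal(mean, sd, size=max(2 * (k - len(out)), 16))
        out = np.concatenate([out, cand[cand >= lod]])
    return out[:k]


def augment(
    summaries: Sequence[TimepointSummary],
    target_n: int = DEFAULT_TARGET_N,
    lod: float = 0.03,
    seed: int = 0,
) -> list[AugmentedTimepoint]:
    """Top up each timepoint to ``target_n`` values with truncated-normal
    Monte Carlo draws parameterised by the observed mean and SD.

    Observed values are carried through unchanged; a timepoint already at or
    above the target gets no simulated values. Deterministic given the seed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    out: list[AugmentedTimepoint] = []
    for s in summaries:
        if s.mean < lod:
            raise AugmentationError(
                f"timepoint {s.time}: mean {s.mean} below LOD {lod} — "
                "should have been excluded by the BLQ policy"
            )
        k = max(0, target_n - s.n_observed)
        sim = _draw_truncated(rng, s.mean, s.sd, lod, k)
        out.append(
            AugmentedTimepoint(s.time, s.values, tuple(float(v) for v in sim))
        )
    return out
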