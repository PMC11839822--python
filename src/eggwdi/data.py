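"""Domain types, censoring policy and delimited-text I/O for egg residue data.

Concentrations are in ng/g (equivalent to ppb by mass); pipeline time is in
days. Depletion analyses use time since the FINAL administered dose: input
files carry study-day times (days since the first dose) and are shifted on
read by ``(n_doses - 1) * interval``, so pre-final-dose eggs carry negative
times.
"""

from __future__ import annotations

import csv
import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("eggwdi")

__all__ = [
    "Matrix",
    "Censor",
    "BlqPolicy",
    "AssayLimits",
    "DoseRegimen",
    "EggObservation",
    "ResidueSeries",
    "FlockDataset",
    "LayingSummary",
    "classify_censor",
    "read_flock",
    "write_flock",
    "apply_blq_policy",
    "build_series",
    "summarize_laying",
]

HOURS_PER_DAY = 24.0

#: Token accepted in the concentration column for a value below the LOD.
BLOD_TOKEN = "BLOD"
#: Token accepted for a value detected but below the LLOQ.
BLOQ_TOKEN = "BLOQ"


class Matrix(str, Enum):
    """Egg fraction an observation was measured in."""

    YOLK = "yolk"
    WHITE = "white"


class Censor(str, Enum):
    """Censoring status of a measured residue concentration."""

    QUANTIFIED = "quantified"
    BELOW_LLOQ_ABOVE_LOD = "below_lloq_above_lod"
    BELOW_LOD = "below_lod"


class BlqPolicy(str, Enum):
    """Which censored records an analysis stage drops.

    ``EXCLUDE_BELOW_LOD`` keeps reported numbers in [LOD, LLOQ) — the policy
    used for depletion and withdrawal-interval work, where only non-detects
    are excluded. ``EXCLUDE_BELOW_LLOQ`` is the stricter option keeping only
    fully quantified values.
    """

    EXCLUDE_BELOW_LOD = "exclude_below_lod"
    EXCLUDE_BELOW_LLOQ = "exclude_below_lloq"


@dataclass(frozen=True)
class AssayLimits:
    """Detection (LOD) and quantification (LLOQ) limits for one matrix, ng/g."""

    matrix: Matrix
    lod: float
    lloq: float

    def __post_init__(self) -> None:
        if not (0.0 < self.lod < self.lloq):
            raise ValueError(
                f"require 0 < lod < lloq, got lod={self.lod}, lloq={self.lloq}"
            )


#: Assay limits of the reference UPLC-fluorescence method for ivermectin.
DEFAULT_LIMITS: Mapping[Matrix, AssayLimits] = {
    Matrix.YOLK: AssayLimits(Matrix.YOLK, lod=0.03, lloq=0.075),
    Matrix.WHITE: AssayLimits(Matrix.WHITE, lod=0.01, lloq=0.025),
}


@dataclass(frozen=True)
class DoseRegimen:
    """Dosing schedule: ``n_doses`` doses of ``dose_per_weight`` mg/kg every
    ``interval`` days."""

    dose_per_weight: float
    interval: float
    n_doses: int
    route: str = "topical"

    def __post_init__(self) -> None:
        if self.dose_per_weight <= 0:
            raise ValueError("dose_per_weight must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValueError("interval must be > 0 for repeated dosing")

    @property
    def final_dose_study_day(self) -> float:
        """Study day of the last administered dose (first dose = day 0)."""
        return (self.n_doses - 1) * self.interval

    def dose_times(self) -> list[float]:
        """Study days on which doses are given."""
        return [i * self.interval for i in range(self.n_doses)]


#: The study regimen: 0.4 mg/kg topically every 7 days for two applications.
DEFAULT_REGIMEN = DoseRegimen(dose_per_weight=0.4, interval=7.0, n_doses=2)


@dataclass(frozen=True)
class EggObservation:
    """One measured egg residue value.

    ``time`` is days since the final administered dose (negative for eggs
    laid between the first and final dose). ``concentration`` is ng/g or
    ``None`` when the assay reported only a censoring token.
    """

    hen_id: str
    time: float
    matrix: Matrix
    concentration: float | None
    censor: Censor

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(f"negative concentration {self.concentration}")
        if self.censor is Censor.QUANTIFIED and self.concentration is None:
            raise ValueError("quantified observation requires a concentration")


def classify_censor(value: float, limits: AssayLimits) -> Censor:
    """Censoring status of a numeric concentration against assay limits.

    Total function of (value, LOD, LLOQ): >= LLOQ quantified; [LOD, LLOQ)
    detected but not quantifiable; < LOD non-detect.
    """
    if value >= limits.lloq:
        return Censor.QUANTIFIED
    if value >= limits.lod:
        return Censor.BELOW_LLOQ_ABOVE_LOD
    return Censor.BELOW_LOD


@dataclass(frozen=True)
class ResidueSeries:
    """Per-hen concentration-time profile for one matrix.

    Times strictly increasing, concentrations > 0 (non-detects are excluded
    before a series is built).
    """

    hen_id: str
    matrix: Matrix
    times: tuple[float, ...]
    concentrations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations length mismatch")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be > 0")

    def __len__(self) -> int:
        return len(self.times)

    def after(self, t0: float) -> "ResidueSeries":
        """Sub-series with time >= t0 (e.g. post-final-dose profile)."""
        keep = [(t, c) for t, c in zip(self.times, self.concentrations) if t >= t0]
        return ResidueSeries(
            self.hen_id,
            self.matrix,
            tuple(t for t, _ in keep),
            tuple(c for _, c in keep),
        )


@dataclass(frozen=True)
class FlockDataset:
    """All egg observations of one study plus assay limits, regimen and
    per-hen body weights (kg)."""

    observations: tuple[EggObservation, ...]
    limits: Mapping[Matrix, AssayLimits]
    regimen: DoseRegimen
    body_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for hen, bw in self.body_weights.items():
            if bw <= 0:
                raise ValueError(f"non-positive body weight for hen {hen}")

    @property
    def hen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            seen.setdefault(obs.hen_id, None)
        return list(seen)

    def subset(self, matrix: Matrix) -> tuple[EggObservation, ...]:
        return tuple(o for o in self.observations if o.matrix is matrix)


class FlockFormatError(ValueError):
    """Malformed input file (missing columns, unparseable rows)."""


class FlockValidationError(ValueError):
    """Well-formed file with invalid values (negative conc, unknown matrix)."""


_REQUIRED_COLUMNS = ("hen_id", "time_days", "matrix", "concentration")


def _parse_row(
    lineno: int,
    row: Mapping[str, str],
    limits: Mapping[Matrix, AssayLimits],
    shift: float,
) -> EggObservation:
    try:
        matrix = Matrix(row["matrix"].strip().lower())
    except ValueError:
        raise FlockValidationError(
            f"line {lineno}: unknown matrix label {row['matrix']!r}"
        ) from None
    try:
        time = float(row["time_days"]) - shift
    except ValueError:
        raise FlockFormatError(
            f"line {lineno}: unparseable time_days {row['time_days']!r}"
        ) from None
    raw = row["concentration"].strip()
    token = raw.upper()
    if token == BLOD_TOKEN:
        return EggObservation(row["hen_id"], time, matrix, None, Censor.BELOW_LOD)
    if token == BLOQ_TOKEN:
        return EggObservation(
            row["hen_id"], time, matrix, None, Censor.BELOW_LLOQ_ABOVE_LOD
        )
    try:
        value = float(raw)
    except ValueError:
        raise FlockFormatError(
            f"line {lineno}: unparseable concentration {raw!r}"
        ) from None
    if value < 0:
        raise FlockValidationError(f"line {lineno}: negative concentration {value}")
    censor = classify_censor(value, limits[matrix])
    if censor is Censor.BELOW_LOD:
        # keep the reported number even though it is a non-detect
        return EggObservation(row["hen_id"], time, matrix, value, censor)
    return EggObservation(row["hen_id"], time, matrix, value, censor)


def read_flock(
    path,
    limits: Mapping[Matrix, AssayLimits] = DEFAULT_LIMITS,
    regimen: DoseRegimen = DEFAULT_REGIMEN,
    body_weights: Mapping[str, float] | None = None,
) -> FlockDataset:
    """Read a flock CSV (hen_id, time_days, matrix, concentration).

    time_days is the study day (since the first dose); observations are
    shifted to days since the final dose. The concentration column accepts a
    number or the tokens BLOD / BLOQ; censoring of numeric values is derived
    from the per-matrix LOD/LLOQ.
    """
    shift = regimen.final_dose_study_day
    observations: list[EggObservation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_REQUIRED_COLUMNS) <= set(
            reader.fieldnames
        ):
            missing = set(_REQUIRED_COLUMNS) - set(reader.fieldnames or ())
            raise FlockFormatError(f"missing required column(s): {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            observations.append(_parse_row(lineno, row, limits, shift))
    return FlockDataset(
        tuple(observations), dict(limits), regimen, dict(body_weights or {})
    )


def write_flock(data: FlockDataset, path) -> None:
    """Write a FlockDataset back to CSV, restoring study-day times.

    Inverse of :func:`read_flock`: numeric values round-trip via repr, tokens
    via BLOD/BLOQ, so read(write(x)) preserves records and censor labels.
    """
    shift = data.regimen.final_dose_study_day
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_REQUIRED_COLUMNS)
        for obs in data.observations:
            if obs.concentration is None:
                conc = BLOD_TOKEN if obs.censor is Censor.BELOW_LOD else BLOQ_TOKEN
            else:
                conc = repr(obs.concentration)
            writer.writerow([obs.hen_id, repr(obs.time + shift), obs.matrix.value, conc])


def apply_blq_policy(data: FlockDataset, policy: BlqPolicy) -> FlockDataset:
    """Drop censored records according to ``policy``.

    Idempotent; never increases the record count. The retained/dropped counts
    are logged for traceability.
    """
    if policy is BlqPolicy.EXCLUDE_BELOW_LOD:
        dropped = {Censor.BELOW_LOD}
    else:
        dropped = {Censor.BELOW_LOD, Censor.BELOW_LLOQ_ABOVE_LOD}
    kept = tuple(o for o in data.observations if o.censor not in dropped)
    logger.info(
        "BLQ policy %s: kept %d of %d records", policy.value, len(kept),
        len(data.observations),
    )
    return replace(data, observations=kept)


def build_series(data: FlockDataset, hen_id: str, matrix: Matrix) -> ResidueSeries:
    """Concentration-time series for one hen/matrix, non-detects excluded.

    Values reported in [LOD, LLOQ) are retained as numbers. Rows without a
    numeric value (censoring tokens) cannot enter a series.
    """
    pts = sorted(
        (o.time, o.concentration)
        for o in data.observations
        if o.hen_id == hen_id
        and o.matrix is matrix
        and o.censor is not Censor.BELOW_LOD
        and o.concentration is not None
    )
    return ResidueSeries(
        hen_id, matrix, tuple(t for t, _ in pts), tuple(c for _, c in pts)
    )


@dataclass(frozen=True)
class LayingSummary:
    """Flock-level lay statistics.

    ``flock_mean_interval`` is the mean over hens of each hen's mean
    consecutive-egg interval; ``hen_mean_intervals`` maps hen to its own
    mean; ``longest_gap`` is the single longest interval observed anywhere;
    ``ceased_hens`` are hens whose last egg precedes the study end by more
    than the configured gap.
    """

    flock_mean_interval: float
    hen_mean_intervals: Mapping[str, float]
    longest_gap: float
    longest_gap_hen: str | None
    ceased_hens: tuple[str, ...]
    last_detection: Mapping[str, float]


def summarize_laying(
    data: FlockDataset,
    study_end: float | None = None,
    cease_gap: float = 10.0,
    stop_run: int = 3,
) -> LayingSummary:
    """Per-hen and flock lay-interval statistics.

    Egg events are the distinct (hen, time) pairs regardless of matrix. Hens
    with fewer than two eggs are excluded from interval statistics with a
    warning. ``last_detection`` records, per hen, the latest time with any
    non-below-LOD yolk or white observation (days since the final dose).

    A hen counts as having ceased laying when her last egg precedes the
    study end by more than ``cease_gap`` days AND her record does not end
    with ``stop_run`` consecutive all-below-LOD eggs — the latter pattern
    means collection was stopped by the depletion stopping rule, not that
    the hen stopped laying.
    """
    lay_times: dict[str, list[float]] = {}
    for obs in data.observations:
        lay_times.setdefault(obs.hen_id, [])
    for hen in lay_times:
        lay_times[hen] = sorted({o.time for o in data.observations if o.hen_id == hen})

    hen_means: dict[str, float] = {}
    longest = 0.0
    longest_hen: str | None = None
    for hen, times in lay_times.items():
        if len(times) < 2:
            warnings.warn(
                f"hen {hen} has < 2 eggs; excluded from interval statistics",
                stacklevel=2,
            )
            continue
        gaps = [t2 - t1 for t1, t2 in zip(times, times[1:])]
        hen_means[hen] = sum(gaps) / len(gaps)
        if max(gaps) > longest:
            longest = max(gaps)
            longest_hen = hen

    if not hen_means:
        flock_mean = math.nan
    else:
        flock_mean = sum(hen_means.values()) / len(hen_means)

    end = study_end
    if end is None:
        end = max((t for ts in lay_times.values() for t in ts), default=0.0)

    def _stopped_by_depletion_rule(hen: str, times: list[float]) -> bool:
        if len(times) < stop_run:
            return False
        for t in times[-stop_run:]:
            eggs = [o for o in data.observations
                    if o.hen_id == hen and o.time == t]
            if any(o.censor is not Censor.BELOW_LOD for o in eggs):
                return False
        return True

    ceased = tuple(
        hen for hen, ts in lay_times.items()
        if ts and end - max(ts) > cease_gap
        and not _stopped_by_depletion_rule(hen, ts)
    )

    last_det: dict[str, float] = {}
    for obs in data.observations:
        if obs.censor is not Censor.BELOW_LOD:
            cur = last_det.get(obs.hen_id)
            if cur is None or obs.time > cur:
                last_det[obs.hen_id] = obs.time

    return LayingSummary(
        flock_mean_interval=flock_mean,
        hen_mean_intervals=hen_means,
        longest_gap=longest,
        longest_gap_hen=longest_hen,
        ceased_hens=ceased,
        last_detection=last_det,
    )
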