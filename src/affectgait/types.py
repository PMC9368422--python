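"""Core domain types shared across the pipeline.

Timestamps are seconds from session start. Affective state is carried either
as a continuous PAD (pleasure-arousal-dominance) triple in [0,1]^3 or as its
discretized SAM region triple in {1..5}^3.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .errors import ValidationError

#: Canonical dimension order used everywhere (matrices, CSV columns, reports).
DIMENSIONS: tuple[str, str, str] = ("pleasure", "arousal", "dominance")

#: Canonical EEG performance-metric order (matrix columns, CSV columns).
METRICS: tuple[str, ...] = (
    "engagement",
    "boredom",
    "excitement",
    "frustration",
    "meditation",
)

#: Number of SAM regions per dimension.
N_REGIONS = 5

MACHINE = "machine"
HUMAN = "human"


class PADVector(NamedTuple):
    """Continuous pleasure-arousal-dominance triple, each component in [0,1]."""

    pleasure: float
    arousal: float
    dominance: float


class PADRegion(NamedTuple):
    """Discretized SAM region triple; each component an integer in 1..5."""

    pleasure: int
    arousal: int
    dominance: int

    def validate(self) -> "PADRegion":
        for dim, value in zip(DIMENSIONS, self):
            if not (isinstance(value, (int,)) or float(value).is_integer()):
                raise ValidationError(f"{dim} region {value!r} is not an integer")
            if not 1 <= int(value) <= N_REGIONS:
                raise ValidationError(
                    f"{dim} region {value} outside 1..{N_REGIONS}"
                )
        return PADRegion(*(int(v) for v in self))


@dataclass(frozen=True)
class MetricSample:
    """One timestamped vector of the five EEG performance metrics.

    All metrics are dimensionless scores in [0,1] as delivered by
    consumer-EEG affect engines; they are not raw band powers.
    """

    t: float
    engagement: float
    boredom: float
    excitement: float
    frustration: float
    meditation: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValidationError(f"sample time {self.t} is negative")
        for name in METRICS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"metric {name}={v} outside [0,1]")

    def values(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in METRICS)


@dataclass(frozen=True)
class AnnotationEvent:
    """A timestamped change-point annotation carrying a full region triple.

    ``source`` is "machine" (EEG-derived) or "human" (SAM video review);
    machine events have an empty ``reviewer_id``.
    """

    session_id: str
    source: str
    reviewer_id: str
    t: float
    region: PADRegion

    def __post_init__(self) -> None:
        if self.source not in (MACHINE, HUMAN):
            raise ValidationError(f"unknown source {self.source!r}")
        if self.source == MACHINE and self.reviewer_id:
            raise ValidationError("machine events must have empty reviewer_id")
        if self.source == HUMAN and not self.reviewer_id:
            raise ValidationError("human events must carry a reviewer_id")
        if self.t < 0:
            raise ValidationError(f"event time {self.t} is negative")
        self.region.validate()


@dataclass(frozen=True)
class AnnotationInterval:
    """Half-open labelled time span [start, end) derived from an event stream."""

    session_id: str
    source: str
    reviewer_id: str
    start: float
    end: float
    region: PADRegion

    def __post_init__(self) -> None:
        if not self.end > self.start >= 0:
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end})"
            )

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class MatchRecord:
    """One machine-interval x human-interval pair with positive overlap."""

    session_id: str
    reviewer_id: str
    overlap_start: float
    overlap_end: float
    machine_region: PADRegion
    human_region: PADRegion

    def __post_init__(self) -> None:
        if not self.overlap_end > self.overlap_start:
            raise ValidationError("match overlap must have positive length")

    @property
    def overlap_length(self) -> float:
        return self.overlap_end - self.overlap_start


@dataclass
class MatchSet:
    """All match records feeding the confusion matrices, plus stream totals."""

    records: list[MatchRecord] = field(default_factory=list)
    machine_event_count: int = 0
    human_event_count: int = 0

    @property
    def match_count(self) -> int:
        return len(self.records)

    def extend(self, other: "MatchSet") -> None:
        self.records.extend(other.records)
        self.machine_event_count += other.machine_event_count
        self.human_event_count += other.human_event_count


def pool_matches(match_sets: Iterable[MatchSet]) -> MatchSet:
    """Concatenate per-session/per-reviewer match sets, summing the totals.

    Records are kept untouched; pooling feeds one confusion matrix per PAD
    dimension over the whole cohort.
    """
    pooled = MatchSet()
    for ms in match_sets:
        pooled.extend(ms)
    return pooled
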