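"""Session timing summaries, active-effort efficiency, and reviewer rotation.

Each therapy session has three timed phases: placing the headsets, the
session proper, and unmounting. Summary statistics use the sample standard
deviation (n-1 denominator) and report whole seconds with half-up rounding,
so half-integer medians round toward the larger value.

Session "efficiency" is the fraction of session time during which the
patient exerts active effort — the quantity contrasted between sessions with
and without a VR headset. The effort flags themselves come from therapy
telemetry and are taken as input; a configurable threshold (default 0.5)
turns a continuous effort series into flags.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import UsageError, ValidationError

ACTIVITIES = ("placing", "session", "unmounting", "total")


@dataclass(frozen=True)
class SessionRecord:
    """Per-patient timings in seconds for the three session phases."""

    patient_id: str
    sex: str
    placing_s: float
    session_s: float
    unmounting_s: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        for name in ("placing_s", "session_s", "unmounting_s"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} is negative")

    @property
    def total_s(self) -> float:
        return self.placing_s + self.session_s + self.unmounting_s


@dataclass(frozen=True)
class SessionStats:
    """Mean / sample SD / median per activity, in whole seconds."""

    mean_s: dict[str, int]
    sample_sd_s: dict[str, int]
    median_s: dict[str, int]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def summarize_sessions(records: Sequence[SessionRecord]) -> SessionStats:
    """Mean, sample standard deviation and median of each phase, rounded half-up."""
    if len(records) < 2:
        raise ValidationError("need at least 2 records (sample SD undefined)")
    columns = {
        "placing": [r.placing_s for r in records],
        "session": [r.session_s for r in records],
        "unmounting": [r.unmounting_s for r in records],
        "total": [r.total_s for r in records],
    }
    mean, sd, median = {}, {}, {}
    for name, values in columns.items():
        arr = np.asarray(values, dtype=float)
        mean[name] = _round_half_up(float(arr.mean()))
        sd[name] = _round_half_up(float(arr.std(ddof=1)))
        median[name] = _round_half_up(float(np.median(arr)))
    return SessionStats(mean_s=mean, sample_sd_s=sd, median_s=median)


@dataclass(frozen=True)
class EfficiencyResult:
    """Fraction of session samples with active patient effort."""

    active_fraction: float
    condition: str  # "VR" or "no-VR"

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValidationError("active fraction outside [0,1]")
        if self.condition not in ("VR", "no-VR"):
            raise ValidationError(f"condition must be VR/no-VR, got {self.condition!r}")


def efficiency(effort_flags: Sequence[bool], condition: str = "no-VR") -> EfficiencyResult:
    """Fraction of samples flagged as active effort (order-invariant)."""
    flags = np.asarray(effort_flags, dtype=bool)
    if flags.size == 0:
        raise ValidationError("efficiency undefined for an empty series")
    return EfficiencyResult(active_fraction=float(flags.mean()), condition=condition)


def flag_effort(effort: Sequence[float], threshold: float = 0.5) -> np.ndarray:
    """Turn a continuous effort series into boolean active-effort flags."""
    return np.asarray(effort, dtype=float) >= threshold


def rotation_schedule(videos: Sequence[str], n_reviewers: int) -> list[list[str]]:
    """Counterbalanced reviewer-to-video viewing orders.

    Reviewer r (1-based) views the video list cyclically shifted left by
    r - 1, so no video is always watched last when reviewers tire. With as
    many reviewers as videos the schedule is a Latin square: every video
    occupies every viewing position exactly once.
    """
    if not videos:
        raise UsageError("need at least one video")
    if n_reviewers < 1:
        raise UsageError("need at least one reviewer")
    n = len(videos)
    return [
        [videos[(r + k) % n] for k in range(n)]
        for r in range(n_reviewers)
    ]
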