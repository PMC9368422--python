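"""Event intervalization and machine-human interval matching.

Reviewers (and the EEG pipeline) annotate only perceived *changes*, so an
event's region triple holds until the next event ("step-hold"): events at
t_1 < t_2 < ... < t_k with session end T become half-open intervals
[t_1, t_2), ..., [t_k, T) that tile [t_1, T).

Matching is by time-span overlap: every machine-interval x human-interval
pair with positive-length intersection is one match, regardless of duration
(an optional minimum-overlap threshold defaults to 0). With several reviewers
per session this pairwise counting yields far more matches than events on
either side. Touching endpoints do not match (half-open convention).
"""
from __future__ import annotations

from typing import Mapping, Sequence

from .config import AlignmentConfig
from .errors import ValidationError
from .types import AnnotationEvent, AnnotationInterval, MatchRecord, MatchSet


def intervalize(events: Sequence[AnnotationEvent],
                session_end: float) -> list[AnnotationInterval]:
    """Convert a sorted event stream into tiling half-open intervals.

    Raises :class:`ValidationError` on an empty stream, unsorted or duplicate
    timestamps, or events at/after ``session_end``.
    """
    if not events:
        raise ValidationError("cannot intervalize an empty event stream")
    times = [e.t for e in events]
    for a, b in zip(times, times[1:]):
        if b <= a:
            raise ValidationError(
                f"event timestamps must be strictly increasing (got {a} then {b})"
            )
    if times[-1] >= session_end:
        raise ValidationError(
            f"event at t={times[-1]} not before session end {session_end}"
        )
    sessions = {e.session_id for e in events}
    sources = {(e.source, e.reviewer_id) for e in events}
    if len(sessions) > 1 or len(sources) > 1:
        raise ValidationError("one stream = one session and one source/reviewer")
    bounds = times + [float(session_end)]
    return [
        AnnotationInterval(
            session_id=e.session_id,
            source=e.source,
            reviewer_id=e.reviewer_id,
            start=bounds[i],
            end=bounds[i + 1],
            region=e.region,
        )
        for i, e in enumerate(events)
    ]


def match_intervals(machine: Sequence[AnnotationInterval],
                    humans: Mapping[str, Sequence[AnnotationInterval]],
                    cfg: AlignmentConfig | None = None) -> MatchSet:
    """Produce one MatchRecord per overlapping machine x human interval pair.

    ``humans`` maps reviewer_id -> that reviewer's interval list. Each list
    must tile its own span and belong to the same session as the machine
    stream. The two-pointer sweep is linear in the total interval count.
    """
    cfg = cfg or AlignmentConfig()
    session_ids = {iv.session_id for iv in machine}
    for intervals in humans.values():
        session_ids |= {iv.session_id for iv in intervals}
    if len(session_ids) > 1:
        raise ValidationError(f"mixed session_ids in match input: {sorted(session_ids)}")

    records: list[MatchRecord] = []
    for reviewer_id, intervals in humans.items():
        i = j = 0
        while i < len(machine) and j < len(intervals):
            m, h = machine[i], intervals[j]
            start = max(m.start, h.start)
            end = min(m.end, h.end)
            if end - start > cfg.min_overlap_s and end > start:
                records.append(MatchRecord(
                    session_id=m.session_id,
                    reviewer_id=reviewer_id,
                    overlap_start=start,
                    overlap_end=end,
                    machine_region=m.region,
                    human_region=h.region,
                ))
            # advance the interval that ends first; ties advance both
            if m.end <= h.end:
                i += 1
            if h.end <= m.end:
                j += 1
    return MatchSet(
        records=records,
        machine_event_count=len(machine),
        human_event_count=sum(len(v) for v in humans.values()),
    )
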