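"""End-to-end orchestration: map -> discretize -> intervalize -> match ->
pool -> confusion -> report -> summary.

The library entry point is :func:`evaluate_cohort`; the CLI and the synthetic
acceptance checks are thin layers over it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .alignment import intervalize, match_intervals
from .config import AlignmentConfig, MappingConfig, PipelineConfig
from .evaluation import (
    ClassReport,
    ConfusionMatrix,
    SummaryStats,
    build_confusion,
    classification_report,
    cross_dimension_summary,
)
from .simulate import SyntheticSession, detect_machine_events, generate_cohort
from .types import DIMENSIONS, AnnotationEvent, MatchSet, MetricSample, pool_matches

log = logging.getLogger("affectgait")


@dataclass
class PipelineResult:
    """Pooled matches plus the per-dimension evaluation artifacts."""

    matches: MatchSet
    confusions: dict[str, ConfusionMatrix]
    reports: dict[str, ClassReport]
    summary: SummaryStats


@dataclass
class SessionInput:
    """One session's observable streams, however they were obtained."""

    session_id: str
    metrics: Sequence[MetricSample]
    reviewer_events: Mapping[str, Sequence[AnnotationEvent]]
    session_end: float
    machine_events: Sequence[AnnotationEvent] | None = None  # derived if absent


def match_session(inp: SessionInput,
                  mapping: MappingConfig | None = None,
                  alignment: AlignmentConfig | None = None) -> MatchSet:
    """Run one session through detection, intervalization and matching."""
    machine_events = inp.machine_events
    if machine_events is None:
        machine_events = detect_machine_events(inp.metrics, inp.session_id, mapping)
    machine = intervalize(machine_events, inp.session_end)
    humans = {
        rid: intervalize(events, inp.session_end)
        for rid, events in inp.reviewer_events.items()
    }
    matches = match_intervals(machine, humans, alignment)
    log.info(
        "session %s: %d machine / %d human events -> %d matches",
        inp.session_id, matches.machine_event_count,
        matches.human_event_count, matches.match_count,
    )
    return matches


def evaluate_matches(matches: MatchSet,
                     weight_by_duration: bool = False) -> PipelineResult:
    """Build per-dimension confusion matrices, reports and the summary."""
    confusions = {
        dim: build_confusion(matches, dim, weight_by_duration=weight_by_duration)
        for dim in DIMENSIONS
    }
    reports = {dim: classification_report(cm) for dim, cm in confusions.items()}
    summary = cross_dimension_summary(reports)
    log.info(
        "pooled %d matches; weighted precision/recall/f1 = %.4f/%.4f/%.4f",
        matches.match_count, summary.mean_weighted_precision,
        summary.mean_weighted_recall, summary.mean_weighted_f1,
    )
    return PipelineResult(
        matches=matches, confusions=confusions, reports=reports, summary=summary
    )


def evaluate_cohort(sessions: Sequence[SessionInput],
                    mapping: MappingConfig | None = None,
                    alignment: AlignmentConfig | None = None,
                    weight_by_duration: bool = False) -> PipelineResult:
    """Match every session, pool across sessions and reviewers, evaluate."""
    pooled = pool_matches(
        match_session(s, mapping, alignment) for s in sessions
    )
    return evaluate_matches(pooled, weight_by_duration=weight_by_duration)


def synthetic_inputs(sessions: Sequence[SyntheticSession]) -> list[SessionInput]:
    """Adapt generated sessions to pipeline inputs (machine events re-derived
    from the metric stream so the full map->discretize path is exercised)."""
    return [
        SessionInput(
            session_id=s.session_id,
            metrics=s.metrics,
            reviewer_events=s.reviewer_events,
            session_end=s.config.session_length_s,
        )
        for s in sessions
    ]


def run_synthetic(cfg: PipelineConfig) -> tuple[list[SyntheticSession], PipelineResult]:
    """Generate a synthetic cohort under ``cfg`` and evaluate it end to end."""
    sessions = generate_cohort(cfg.synthetic, cfg.n_sessions, cfg.mapping)
    result = evaluate_cohort(
        synthetic_inputs(sessions),
        mapping=cfg.mapping,
        alignment=cfg.alignment,
        weight_by_duration=cfg.alignment.weight_by_duration,
    )
    return sessions, result
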