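"""CSV/TSV/JSON readers and writers for the pipeline artifacts.

All files are UTF-8 CSV with a header row and "." decimal separator;
timestamps are seconds from session start. Readers validate ranges row by
row and report the offending line number.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ParseError, ValidationError
from .evaluation import ClassReport, ConfusionMatrix, SummaryStats, heatmap_matrix
from .sessions import SessionRecord, SessionStats
from .types import (
    DIMENSIONS,
    METRICS,
    AnnotationEvent,
    MatchRecord,
    MatchSet,
    MetricSample,
    PADRegion,
)

METRIC_COLUMNS = ("t_s",) + METRICS
EVENT_COLUMNS = ("session_id", "source", "reviewer_id", "t_s",
                 "pleasure_region", "arousal_region", "dominance_region")
MATCH_COLUMNS = ("session_id", "reviewer_id", "overlap_start_s", "overlap_end_s",
                 "machine_pleasure", "machine_arousal", "machine_dominance",
                 "human_pleasure", "human_arousal", "human_dominance")
TIMING_COLUMNS = ("patient_id", "sex", "placing_s", "session_s", "unmounting_s")


def _open_reader(path: str | Path, expected: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))
    handle = path.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle)
    if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != list(expected):
        handle.close()
        raise ParseError(
            f"header must be {','.join(expected)}", path=str(path), line=1
        )
    return handle, reader


def _parse_float(row: dict, key: str, path: str, line: int) -> float:
    try:
        return float(row[key])
    except (TypeError, ValueError) as exc:
        raise ParseError(f"bad value for {key}: {row[key]!r}",
                         path=path, line=line) from exc


def _parse_region(row: dict, key: str, path: str, line: int) -> int:
    value = _parse_float(row, key, path, line)
    if not value.is_integer():
        raise ParseError(f"{key} must be an integer, got {row[key]!r}",
                         path=path, line=line)
    return int(value)


def read_metric_stream(path: str | Path) -> list[MetricSample]:
    """Read a metric CSV; rows are validated to [0,1] and returned time-sorted."""
    handle, reader = _open_reader(path, METRIC_COLUMNS)
    samples = []
    with handle:
        for line, row in enumerate(reader, start=2):
            values = {key: _parse_float(row, key, str(path), line)
                      for key in METRIC_COLUMNS}
            try:
                samples.append(MetricSample(values["t_s"],
                                            *(values[m] for m in METRICS)))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line}: {exc}") from exc
    return sorted(samples, key=lambda s: s.t)


def write_metric_stream(samples: Sequence[MetricSample], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(METRIC_COLUMNS)
        for s in samples:
            writer.writerow([repr(float(s.t))] + [repr(float(v)) for v in s.values()])


def read_event_stream(path: str | Path) -> list[AnnotationEvent]:
    """Read an annotation-event CSV (machine or human), time-sorted."""
    handle, reader = _open_reader(path, EVENT_COLUMNS)
    events = []
    with handle:
        for line, row in enumerate(reader, start=2):
            t = _parse_float(row, "t_s", str(path), line)
            region = PADRegion(*(
                _parse_region(row, f"{dim}_region", str(path), line)
                for dim in DIMENSIONS
            ))
            try:
                events.append(AnnotationEvent(
                    session_id=row["session_id"],
                    source=row["source"],
                    reviewer_id=row["reviewer_id"] or "",
                    t=t,
                    region=region,
                ))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line}: {exc}") from exc
    return sorted(events, key=lambda e: (e.session_id, e.reviewer_id, e.t))


def write_event_stream(events: Sequence[AnnotationEvent], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(EVENT_COLUMNS)
        for e in events:
            writer.writerow([e.session_id, e.source, e.reviewer_id,
                             repr(float(e.t)), *e.region])


def write_matches(matches: MatchSet, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(MATCH_COLUMNS)
        for r in matches.records:
            writer.writerow([
                r.session_id, r.reviewer_id,
                repr(float(r.overlap_start)), repr(float(r.overlap_end)),
                *r.machine_region, *r.human_region,
            ])


def read_matches(path: str | Path) -> MatchSet:
    handle, reader = _open_reader(path, MATCH_COLUMNS)
    records = []
    with handle:
        for line, row in enumerate(reader, start=2):
            try:
                records.append(MatchRecord(
                    session_id=row["session_id"],
                    reviewer_id=row["reviewer_id"],
                    overlap_start=_parse_float(row, "overlap_start_s", str(path), line),
                    overlap_end=_parse_float(row, "overlap_end_s", str(path), line),
                    machine_region=PADRegion(*(
                        _parse_region(row, f"machine_{d}", str(path), line)
                        for d in DIMENSIONS)).validate(),
                    human_region=PADRegion(*(
                        _parse_region(row, f"human_{d}", str(path), line)
                        for d in DIMENSIONS)).validate(),
                ))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line}: {exc}") from exc
    return MatchSet(records=records)


def read_session_records(path: str | Path) -> list[SessionRecord]:
    handle, reader = _open_reader(path, TIMING_COLUMNS)
    records = []
    with handle:
        for line, row in enumerate(reader, start=2):
            try:
                records.append(SessionRecord(
                    patient_id=row["patient_id"],
                    sex=row["sex"],
                    placing_s=_parse_float(row, "placing_s", str(path), line),
                    session_s=_parse_float(row, "session_s", str(path), line),
                    unmounting_s=_parse_float(row, "unmounting_s", str(path), line),
                ))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{line}: {exc}") from exc
    return records


def write_session_records(records: Sequence[SessionRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(TIMING_COLUMNS)
        for r in records:
            writer.writerow([r.patient_id, r.sex, repr(float(r.placing_s)),
                             repr(float(r.session_s)), repr(float(r.unmounting_s))])


def format_report(report: ClassReport) -> str:
    """Render a report as a TSV laid out like the published tables
    (five region rows, accuracy, macro avg, weighted avg; 6 decimals)."""
    lines = ["Region\tPrecision\tRecall\tF1-Score\tSupport"]
    for r in range(1, 6):
        lines.append("\t".join([str(r)] + [
            f"{v:.6f}" for v in (report.precision[r - 1], report.recall[r - 1],
                                 report.f1[r - 1], report.support[r - 1])
        ]))
    lines.append("accuracy" + f"\t{report.accuracy:.6f}" * 4)
    lines.append("macro avg\t" + "\t".join(
        [f"{v:.6f}" for v in report.macro_avg] + [f"{report.total_support:,.6f}"]))
    lines.append("weighted avg\t" + "\t".join(
        [f"{v:.6f}" for v in report.weighted_avg] + [f"{report.total_support:,.6f}"]))
    return "\n".join(lines) + "\n"


def write_report(report: ClassReport, path: str | Path) -> None:
    Path(path).write_text(format_report(report), encoding="utf-8")


def write_heatmap(cm: ConfusionMatrix, path: str | Path,
                  normalize: str = "none") -> None:
    matrix = heatmap_matrix(cm, normalize=normalize)
    header = ",".join(["actual\\predicted"] + [str(c) for c in range(1, 6)])
    rows = [header] + [
        ",".join([str(r + 1)] + [f"{v:.6f}" for v in matrix[r]]) for r in range(5)
    ]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def write_summary(summary: SummaryStats, matches: MatchSet,
                  path: str | Path) -> None:
    payload = {
        "mean_weighted_precision": summary.mean_weighted_precision,
        "mean_weighted_recall": summary.mean_weighted_recall,
        "mean_weighted_f1": summary.mean_weighted_f1,
        "formatted": summary.formatted(),
        "machine_event_count": matches.machine_event_count,
        "human_event_count": matches.human_event_count,
        "match_count": matches.match_count,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def write_session_stats(stats: SessionStats, path: str | Path) -> None:
    """Timing summary as a TSV shaped like the published timing table footer."""
    lines = ["Statistic\tPlacing\tSession\tUnmounting\tTotal"]
    for name, values in (("Average", stats.mean_s),
                         ("Std Dev", stats.sample_sd_s),
                         ("Median", stats.median_s)):
        lines.append("\t".join([name] + [
            str(values[a]) for a in ("placing", "session", "unmounting", "total")
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
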