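"""Published summary tables from an eight-patient robot-assisted gait therapy
affect-annotation study, kept as plain data.

These are the study's *reported* statistics — per-dimension classification
report rows (precision / recall / F1 / support per SAM region, plus macro and
weighted averages), per-patient session timings, and the reviewer-video
rotation grid. The raw recordings behind them are not distributed, but the
report rows pin down each confusion matrix's diagonal, row sums and column
sums, so the full report arithmetic can be reconstructed and re-verified with
:func:`affectgait.evaluation.confusion_from_report_rows`.
"""
from __future__ import annotations

from .sessions import SessionRecord

#: Reviewer-video rotation grid: row r = viewing order of reviewer r+1.
ROTATION_VIDEOS = ("AGS1", "AGS2", "AGS3", "AGS4", "GDL1", "GDL2", "GDL3", "GDL4")
ROTATION_GRID = (
    ("AGS1", "AGS2", "AGS3", "AGS4", "GDL1", "GDL2", "GDL3", "GDL4"),
    ("AGS2", "AGS3", "AGS4", "GDL1", "GDL2", "GDL3", "GDL4", "AGS1"),
    ("AGS3", "AGS4", "GDL1", "GDL2", "GDL3", "GDL4", "AGS1", "AGS2"),
    ("AGS4", "GDL1", "GDL2", "GDL3", "GDL4", "AGS1", "AGS2", "AGS3"),
    ("GDL1", "GDL2", "GDL3", "GDL4", "AGS1", "AGS2", "AGS3", "AGS4"),
    ("GDL2", "GDL3", "GDL4", "AGS1", "AGS2", "AGS3", "AGS4", "GDL1"),
    ("GDL3", "GDL4", "AGS1", "AGS2", "AGS3", "AGS4", "GDL1", "GDL2"),
    ("GDL4", "AGS1", "AGS2", "AGS3", "AGS4", "GDL1", "GDL2", "GDL3"),
)

#: Per-patient phase timings in seconds (patient, sex, placing, session, unmounting).
SESSION_TIMINGS = (
    SessionRecord("1", "male", 88, 2075, 150),
    SessionRecord("2", "female", 188, 2696, 77),
    SessionRecord("3", "male", 111, 1640, 91),
    SessionRecord("4", "male", 129, 1996, 100),
    SessionRecord("5", "male", 75, 1716, 118),
    SessionRecord("6", "female", 233, 1513, 74),
    SessionRecord("7", "female", 194, 1655, 86),
    SessionRecord("8", "female", 310, 2378, 153),
)

#: Reported timing summary cells (whole seconds), activity -> value.
REPORTED_TIMING_SUMMARY = {
    "mean": {"placing": 166, "session": 1959, "unmounting": 106, "total": 2231},
    "sample_sd": {"placing": 80, "session": 412, "unmounting": 31, "total": 451},
    "median": {"placing": 159, "session": 1856, "unmounting": 96, "total": 2080},
}

#: Reported per-dimension classification reports over 11,852 pooled matches.
#: Regions are ordered 1..5; averages are (precision, recall, f1).
REPORTED_CLASS_REPORTS = {
    "pleasure": {
        "precision": (0.0, 0.959236, 0.0, 0.999723, 1.0),
        "recall": (0.0, 0.895363, 0.0, 0.842093, 0.5),
        "f1": (0.0, 0.926199, 0.0, 0.914163, 0.666667),
        "support": (0.0, 7569.0, 0.0, 4281.0, 2.0),
        "accuracy": 0.876055,
        "macro_avg": (0.591792, 0.447491, 0.501406),
        "weighted_avg": (0.973867, 0.876055, 0.921808),
        "total_support": 11852.0,
    },
    "arousal": {
        "precision": (0.0, 0.864483, 0.002660, 1.0, 0.0),
        "recall": (0.0, 0.907870, 1.0, 0.822640, 0.0),
        "f1": (0.0, 0.885645, 0.005305, 0.902691, 0.0),
        "support": (0.0, 4244.0, 2.0, 7606.0, 0.0),
        "accuracy": 0.853189,
        "macro_avg": (0.466786, 0.682627, 0.448410),
        "weighted_avg": (0.951305, 0.853189, 0.896436),
        "total_support": 11852.0,
    },
    "dominance": {
        "precision": (0.0, 1.0, 0.002494, 0.0, 0.0),
        "recall": (0.0, 0.906751, 1.0, 0.0, 0.0),
        "f1": (0.0, 0.951095, 0.004975, 0.0, 0.0),
        "support": (0.0, 11850.0, 2.0, 0.0, 0.0),
        "accuracy": 0.906767,
        "macro_avg": (0.334165, 0.635584, 0.318690),
        "weighted_avg": (0.999832, 0.906767, 0.950936),
        "total_support": 11852.0,
    },
}

#: Reported cross-dimension summary, formatted to 0.1% as published.
REPORTED_SUMMARY = {"precision": "97.5%", "recall": "87.9%", "f1": "92.3%"}
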