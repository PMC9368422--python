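"""Imbalanced multi-class agreement evaluation.

For each PAD dimension a 5x5 confusion matrix is tallied over match records,
with the EEG-derived region as the *actual* class (rows) and the human SAM
annotation as the *prediction* (columns). The classification report follows
the standard imbalanced-evaluation conventions:

    precision_r = diag_r / colsum_r      (0 when the column is empty)
    recall_r    = diag_r / rowsum_r      (0 when the row is empty)
    f1_r        = harmonic mean          (0 when precision + recall = 0)
    support_r   = rowsum_r
    accuracy    = trace / total          (== support-weighted mean recall)

The macro average is the unweighted mean over the *observed* label set (the
union of non-empty actual and predicted labels) unless an explicit label set
is supplied; the weighted average is the support-weighted mean over all rows.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyMatrixError, UsageError, ValidationError
from .types import DIMENSIONS, N_REGIONS, MatchSet


@dataclass
class ConfusionMatrix:
    """Per-dimension 5x5 agreement matrix; rows = actual (EEG), cols = predicted (SAM)."""

    dimension: str
    counts: np.ndarray  # shape (5, 5), non-negative

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_REGIONS, N_REGIONS):
            raise ValidationError(f"confusion matrix must be {N_REGIONS}x{N_REGIONS}")
        if (self.counts < 0).any():
            raise ValidationError("confusion matrix has negative cells")
        if self.dimension not in DIMENSIONS:
            raise UsageError(f"unknown dimension {self.dimension!r}")

    @property
    def total(self) -> float:
        return self.counts.sum()

    def observed_labels(self) -> list[int]:
        """Labels with non-zero actual or predicted mass, ascending."""
        nz = (self.counts.sum(axis=1) > 0) | (self.counts.sum(axis=0) > 0)
        return [int(i) + 1 for i in np.flatnonzero(nz)]


@dataclass
class ClassReport:
    """Per-class precision/recall/F1/support plus accuracy and averages."""

    dimension: str
    precision: np.ndarray       # length 5, indexed region-1
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro_avg: tuple[float, float, float]      # precision, recall, f1
    weighted_avg: tuple[float, float, float]
    total_support: float
    labels: tuple[int, ...]                    # labels the macro averages over

    def to_frame(self) -> pd.DataFrame:
        """Report as a table shaped like the published per-dimension reports."""
        rows = {}
        for r in range(1, N_REGIONS + 1):
            rows[str(r)] = [self.precision[r - 1], self.recall[r - 1],
                            self.f1[r - 1], self.support[r - 1]]
        rows["accuracy"] = [self.accuracy] * 4
        rows["macro avg"] = [*self.macro_avg, self.total_support]
        rows["weighted avg"] = [*self.weighted_avg, self.total_support]
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["Precision", "Recall", "F1-Score", "Support"],
        ).rename_axis("Region")


def build_confusion(matches: MatchSet, dimension: str,
                    weight_by_duration: bool = False) -> ConfusionMatrix:
    """Tally match records into the dimension's confusion matrix.

    Matches are unit-weighted by default; with ``weight_by_duration`` each
    record contributes its overlap length in seconds instead.
    """
    if dimension not in DIMENSIONS:
        raise UsageError(f"unknown dimension {dimension!r}")
    if matches.match_count == 0:
        raise EmptyMatrixError("cannot build a confusion matrix from zero matches")
    dim_idx = DIMENSIONS.index(dimension)
    actual = np.fromiter((rec.machine_region[dim_idx] for rec in matches.records),
                         dtype=np.int64, count=matches.match_count)
    predicted = np.fromiter((rec.human_region[dim_idx] for rec in matches.records),
                            dtype=np.int64, count=matches.match_count)
    if weight_by_duration:
        weights = np.fromiter((rec.overlap_length for rec in matches.records),
                              dtype=float, count=matches.match_count)
        counts = np.zeros((N_REGIONS, N_REGIONS))
    else:
        weights = np.ones(matches.match_count, dtype=np.int64)
        counts = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int64)
    np.add.at(counts, (actual - 1, predicted - 1), weights)
    return ConfusionMatrix(dimension=dimension, counts=counts)


def classification_report(m: ConfusionMatrix,
                          labels: Iterable[int] | None = None) -> ClassReport:
    """Compute the per-class report with zero-division -> 0 conventions.

    ``labels`` fixes the macro-average label set; by default the observed
    labels are used. Accuracy and the weighted averages never depend on it.
    """
    total = m.total
    if total <= 0:
        raise EmptyMatrixError("classification report undefined for an empty matrix")
    counts = m.counts.astype(float)
    diag = np.diag(counts)
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
        denom = 2 * diag + (colsum - diag) + (rowsum - diag)
        f1 = np.where(denom > 0, 2 * diag / np.where(denom > 0, denom, 1), 0.0)
    accuracy = float(diag.sum() / total)
    if labels is None:
        label_list = m.observed_labels()
    else:
        label_list = sorted(int(x) for x in labels)
        if not label_list or not all(1 <= x <= N_REGIONS for x in label_list):
            raise UsageError(f"labels must be a non-empty subset of 1..{N_REGIONS}")
    idx = np.asarray(label_list) - 1
    macro = tuple(float(v[idx].mean()) for v in (precision, recall, f1))
    weighted = tuple(float((v * rowsum).sum() / total) for v in (precision, recall, f1))
    return ClassReport(
        dimension=m.dimension,
        precision=precision,
        recall=recall,
        f1=f1,
        support=rowsum,
        accuracy=accuracy,
        macro_avg=macro,
        weighted_avg=weighted,
        total_support=float(total),
        labels=tuple(label_list),
    )


def heatmap_matrix(m: ConfusionMatrix, normalize: str = "none") -> np.ndarray:
    """Counts, or counts normalized by row/column sums (empty lines stay zero)."""
    counts = m.counts.astype(float)
    if normalize == "none":
        return counts
    if normalize == "row":
        sums = counts.sum(axis=1, keepdims=True)
    elif normalize == "column":
        sums = counts.sum(axis=0, keepdims=True)
    else:
        raise UsageError(f"normalize must be none/row/column, got {normalize!r}")
    return np.divide(counts, sums, out=np.zeros_like(counts), where=sums > 0)


@dataclass(frozen=True)
class SummaryStats:
    """Weighted-average metrics averaged (unweighted) over the three PAD dimensions."""

    mean_weighted_precision: float
    mean_weighted_recall: float
    mean_weighted_f1: float

    def formatted(self) -> dict[str, str]:
        return {
            "precision": f"{100 * self.mean_weighted_precision:.1f}%",
            "recall": f"{100 * self.mean_weighted_recall:.1f}%",
            "f1": f"{100 * self.mean_weighted_f1:.1f}%",
        }


def cross_dimension_summary(reports: Mapping[str, ClassReport]) -> SummaryStats:
    """Average the three per-dimension weighted-avg rows into one summary."""
    if set(reports) != set(DIMENSIONS):
        raise UsageError(f"need exactly one report per dimension {DIMENSIONS}")
    stacked = np.asarray([reports[d].weighted_avg for d in DIMENSIONS])
    means = stacked.mean(axis=0)
    return SummaryStats(*(float(x) for x in means))


def confusion_from_report_rows(dimension: str,
                               precision: Sequence[float],
                               recall: Sequence[float],
                               support: Sequence[float],
                               macro_precision: float | None = None,
                               ) -> tuple[ConfusionMatrix, tuple[int, ...]]:
    """Reconstruct an integer confusion matrix from printed report rows.

    Inverts the report arithmetic: diagonal_r = round(recall_r * support_r)
    and, for classes with positive precision, colsum_r = round(diag_r /
    precision_r). Off-diagonal mass (rows' support minus diagonal) is first
    routed to columns with a known colsum deficit, then spread evenly over
    the remaining labels of the observed set. The printed rows alone do not
    reveal how many labels the original evaluation observed; when
    ``macro_precision`` is given, that count is recovered as
    round(sum(precision) / macro_precision) and the observed set is extended
    with the smallest unused labels. Returns the matrix and the label set.
    """
    precision = np.asarray(precision, dtype=float)
    recall = np.asarray(recall, dtype=float)
    support = np.asarray(support, dtype=float)
    diag = np.rint(recall * support).astype(np.int64)
    rowsum = np.rint(support).astype(np.int64)
    colsum = np.full(N_REGIONS, -1, dtype=np.int64)  # -1 = unconstrained
    for r in range(N_REGIONS):
        if precision[r] > 0:
            colsum[r] = int(np.rint(diag[r] / precision[r]))
        elif diag[r] > 0:
            raise ValidationError(f"region {r+1}: zero precision with nonzero diagonal")

    observed = {r + 1 for r in range(N_REGIONS) if rowsum[r] > 0 or colsum[r] > 0}
    if macro_precision is not None and macro_precision > 0:
        n_obs = int(np.rint(precision.sum() / macro_precision))
        if not len(observed) <= n_obs <= N_REGIONS:
            raise ValidationError(
                f"macro precision implies {n_obs} observed labels, "
                f"inconsistent with {sorted(observed)}"
            )
        for cand in range(1, N_REGIONS + 1):
            if len(observed) >= n_obs:
                break
            observed.add(cand)
    labels = tuple(sorted(observed))

    counts = np.zeros((N_REGIONS, N_REGIONS), dtype=np.int64)
    np.fill_diagonal(counts, diag)
    row_slack = rowsum - diag
    placed = np.zeros_like(counts)
    # first satisfy known column deficits, never touching a row's own diagonal
    col_need = np.where(colsum >= 0, colsum - diag, 0)
    for c in np.argsort(-col_need):
        for r in range(N_REGIONS):
            if col_need[c] <= 0:
                break
            if r == c or row_slack[r] <= 0:
                continue
            put = min(row_slack[r], col_need[c])
            placed[r, c] += put
            row_slack[r] -= put
            col_need[c] -= put
    # repair: a column may be left needing mass while the only remaining row
    # slack sits on its own diagonal row; reroute a balanced swap through a
    # previously filled off-diagonal cell
    while (col_need > 0).any():
        c = int(np.argmax(col_need))
        if row_slack[c] <= 0:
            raise ValidationError(
                "report rows are inconsistent: column sums unsatisfiable")
        for r2 in range(N_REGIONS):
            if r2 == c or col_need[c] <= 0:
                continue
            for c2 in range(N_REGIONS):
                if c2 == c or placed[r2, c2] <= 0:
                    continue
                amt = min(col_need[c], placed[r2, c2], row_slack[c])
                if amt <= 0:
                    continue
                placed[r2, c2] -= amt
                placed[r2, c] += amt
                placed[c, c2] += amt
                row_slack[c] -= amt
                col_need[c] -= amt
        if col_need[c] > 0:
            raise ValidationError(
                "report rows are inconsistent: column sums unsatisfiable")
    counts += placed
    # remaining mass goes evenly to unconstrained columns of the observed set
    free_cols = [l - 1 for l in labels if colsum[l - 1] < 0]
    for r in np.flatnonzero(row_slack):
        targets = [c for c in free_cols if c != r]
        if not targets:
            raise ValidationError(f"row {r+1}: leftover mass but no free column")
        share = int(row_slack[r]) // len(targets)
        extra = int(row_slack[r]) - share * len(targets)
        for k, c in enumerate(targets):
            counts[r, c] += share + (1 if k < extra else 0)
    return ConfusionMatrix(dimension=dimension, counts=counts), labels
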