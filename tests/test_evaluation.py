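"""Confusion tabulation and imbalanced classification reporting."""
import numpy as np
import pytest

from affectgait import (
    ConfusionMatrix,
    EmptyMatrixError,
    MatchRecord,
    MatchSet,
    PADRegion,
    UsageError,
    build_confusion,
    classification_report,
    confusion_from_report_rows,
    cross_dimension_summary,
    heatmap_matrix,
)
from affectgait.types import DIMENSIONS


def match(machine, human, rid="R1"):
    return MatchRecord(session_id="S1", reviewer_id=rid,
                       overlap_start=0.0, overlap_end=1.0,
                       machine_region=PADRegion(*machine),
                       human_region=PADRegion(*human))


def brute_force_report(counts):
    """Independent tally-and-divide oracle with zero-division -> 0."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    out = {"precision": [], "recall": [], "f1": [], "support": []}
    for r in range(5):
        tp = counts[r, r]
        fp = counts[:, r].sum() - tp
        fn = counts[r, :].sum() - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        q = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
        out["precision"].append(p)
        out["recall"].append(q)
        out["f1"].append(f)
        out["support"].append(tp + fn)
    out["accuracy"] = np.trace(counts) / total
    out["weighted"] = [
        sum(out[k][r] * out["support"][r] for r in range(5)) / total
        for k in ("precision", "recall", "f1")
    ]
    observed = [r for r in range(5)
                if counts[r].sum() > 0 or counts[:, r].sum() > 0]
    out["macro"] = [np.mean([out[k][r] for r in observed])
                    for k in ("precision", "recall", "f1")]
    return out


# Confusion structure consistent with the published pleasure report rows
PLEASURE_COUNTS = np.array([
    [0, 0, 0, 0, 0],
    [400, 6777, 391, 1, 0],
    [0, 0, 0, 0, 0],
    [300, 287, 89, 3605, 0],
    [0, 1, 0, 0, 1],
])


class TestBuildConfusion:
    def test_single_cell(self):
        ms = MatchSet(records=[match((2, 1, 1), (2, 1, 1))] * 3)
        cm = build_confusion(ms, "pleasure")
        assert cm.counts[1, 1] == 3 and cm.counts.sum() == 3

    def test_enumeration(self):
        ms = MatchSet(records=[match((2, 1, 1), (2, 1, 1)),
                               match((2, 1, 1), (4, 1, 1)),
                               match((4, 1, 1), (4, 1, 1))])
        cm = build_confusion(ms, "pleasure")
        assert cm.counts[1, 1] == 1 and cm.counts[1, 3] == 1 and cm.counts[3, 3] == 1
        assert cm.counts.sum() == 3

    def test_matches_brute_force_tally(self, rng):
        actual = rng.integers(1, 6, size=10000)
        predicted = rng.integers(1, 6, size=10000)
        ms = MatchSet(records=[match((a, 1, 1), (p, 1, 1))
                               for a, p in zip(actual, predicted)])
        cm = build_confusion(ms, "pleasure")
        expected = np.zeros((5, 5), dtype=int)
        for a, p in zip(actual, predicted):
            expected[a - 1, p - 1] += 1
        np.testing.assert_array_equal(cm.counts, expected)

    def test_empty_rejected(self):
        with pytest.raises(EmptyMatrixError):
            build_confusion(MatchSet(), "pleasure")

    def test_duration_weighted_mode(self):
        recs = [MatchRecord("S1", "R1", 0.0, 2.5, PADRegion(2, 1, 1),
                            PADRegion(2, 1, 1)),
                MatchRecord("S1", "R1", 2.5, 10.0, PADRegion(2, 1, 1),
                            PADRegion(4, 1, 1))]
        cm = build_confusion(MatchSet(records=recs), "pleasure",
                             weight_by_duration=True)
        assert cm.counts[1, 1] == pytest.approx(2.5)
        assert cm.counts[1, 3] == pytest.approx(7.5)


class TestClassificationReport:
    def test_reconstructed_pleasure_table(self):
        """The published pleasure rows are reproduced to 6 decimals."""
        rep = classification_report(ConfusionMatrix("pleasure", PLEASURE_COUNTS))
        np.testing.assert_allclose(
            rep.precision, [0, 0.959236, 0, 0.999723, 1.0], atol=5e-7)
        np.testing.assert_allclose(
            rep.recall, [0, 0.895363, 0, 0.842093, 0.5], atol=5e-7)
        np.testing.assert_allclose(
            rep.f1, [0, 0.926199, 0, 0.914163, 0.666667], atol=5e-7)
        assert rep.accuracy == pytest.approx(0.876055, abs=5e-7)
        assert rep.macro_avg[0] == pytest.approx(0.591792, abs=5e-7)
        assert rep.weighted_avg[0] == pytest.approx(0.973867, abs=5e-7)

    def test_perfect_classifier(self):
        rep = classification_report(ConfusionMatrix("arousal", np.eye(5) * 7))
        assert rep.accuracy == 1.0
        assert rep.weighted_avg == (1.0, 1.0, 1.0)

    def test_accuracy_equals_weighted_recall(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 40, size=(5, 5))
            if counts.sum() == 0:
                continue
            rep = classification_report(ConfusionMatrix("pleasure", counts))
            assert rep.accuracy == pytest.approx(rep.weighted_avg[1])

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 50, size=(5, 5))
            counts[rng.integers(0, 5)] = 0  # force some empty rows
            if counts.sum() == 0:
                continue
            rep = classification_report(ConfusionMatrix("dominance", counts))
            ref = brute_force_report(counts)
            np.testing.assert_allclose(rep.precision, ref["precision"], atol=1e-12)
            np.testing.assert_allclose(rep.recall, ref["recall"], atol=1e-12)
            np.testing.assert_allclose(rep.f1, ref["f1"], atol=1e-12)
            np.testing.assert_allclose(rep.macro_avg, ref["macro"], atol=1e-12)
            np.testing.assert_allclose(rep.weighted_avg, ref["weighted"], atol=1e-12)
            assert rep.accuracy == pytest.approx(ref["accuracy"])

    def test_explicit_label_set_controls_macro(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[1, 1] = 8
        counts[1, 2] = 2
        rep_obs = classification_report(ConfusionMatrix("pleasure", counts))
        rep_all = classification_report(ConfusionMatrix("pleasure", counts),
                                        labels=range(1, 6))
        assert rep_obs.labels == (2, 3)
        assert rep_obs.macro_avg[0] == pytest.approx(0.5)
        assert rep_all.macro_avg[0] == pytest.approx(0.2)
        assert rep_obs.weighted_avg == rep_all.weighted_avg

    def test_empty_matrix_rejected(self):
        with pytest.raises(EmptyMatrixError):
            classification_report(ConfusionMatrix("pleasure", np.zeros((5, 5))))


class TestHeatmap:
    def test_row_normalized_rows_sum_to_one(self):
        hm = heatmap_matrix(ConfusionMatrix("pleasure", PLEASURE_COUNTS), "row")
        sums = hm.sum(axis=1)
        for r in range(5):
            if PLEASURE_COUNTS[r].sum() > 0:
                assert sums[r] == pytest.approx(1.0)
            else:
                assert sums[r] == 0.0

    def test_none_is_identity(self):
        hm = heatmap_matrix(ConfusionMatrix("pleasure", PLEASURE_COUNTS), "none")
        np.testing.assert_array_equal(hm, PLEASURE_COUNTS)

    def test_column_normalized_diagonal_is_precision(self):
        hm = heatmap_matrix(ConfusionMatrix("pleasure", PLEASURE_COUNTS), "column")
        assert hm[1, 1] == pytest.approx(0.959236, abs=5e-7)

    def test_unknown_mode_rejected(self):
        with pytest.raises(UsageError):
            heatmap_matrix(ConfusionMatrix("pleasure", PLEASURE_COUNTS), "total")


class TestSummary:
    def _reports(self, counts_by_dim):
        return {dim: classification_report(ConfusionMatrix(dim, counts))
                for dim, counts in counts_by_dim.items()}

    def test_constant_mean(self):
        counts = np.eye(5) * 4
        reports = self._reports({d: counts for d in DIMENSIONS})
        summary = cross_dimension_summary(reports)
        assert summary.mean_weighted_precision == pytest.approx(1.0)

    def test_missing_dimension_rejected(self):
        counts = np.eye(5)
        reports = self._reports({"pleasure": counts, "arousal": counts})
        with pytest.raises(UsageError):
            cross_dimension_summary(reports)

    def test_formatting_to_tenth_of_percent(self):
        counts = np.zeros((5, 5))
        counts[1, 1], counts[1, 2] = 879, 121
        reports = self._reports({d: counts for d in DIMENSIONS})
        assert cross_dimension_summary(reports).formatted()["recall"] == "87.9%"


class TestReconstruction:
    def test_round_trips_through_report(self, rng):
        """reconstruct(report(M)) reproduces report(M) for random matrices."""
        for _ in range(30):
            counts = rng.integers(0, 60, size=(5, 5))
            counts[rng.integers(0, 5)] = 0
            if counts.sum() == 0 or np.trace(counts) == 0:
                continue
            rep = classification_report(ConfusionMatrix("arousal", counts))
            cm2, labels = confusion_from_report_rows(
                "arousal", rep.precision, rep.recall, rep.support,
                macro_precision=rep.macro_avg[0] or None)
            rep2 = classification_report(cm2, labels=labels)
            np.testing.assert_allclose(rep2.precision, rep.precision, atol=1e-6)
            np.testing.assert_allclose(rep2.recall, rep.recall, atol=1e-6)
            np.testing.assert_allclose(rep2.support, rep.support, atol=1e-6)
            np.testing.assert_allclose(rep2.weighted_avg, rep.weighted_avg,
                                       atol=1e-6)
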