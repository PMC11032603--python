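import numpy as np
import pytest

from mirtarget.metrics import (
    ConfusionCounts,
    MetricsReport,
    average_reports,
    compute_metrics,
    confusion,
    curve_metrics,
    evaluate,
    percent_display,
)

# published per-test-set values used as fixed inputs for the averaging and
# score arithmetic (percent scale)
NH1_ROW = (96.47, 95.85, 97.10, 97.06, 95.90, 96.45)
NH2_ROW = (94.89, 94.47, 95.30, 95.25, 94.53, 94.86)
TEN_SET_ACCURACY = (80.15, 80.42, 80.07, 78.35, 79.75, 79.55, 79.21, 81.08, 80.63, 80.51)
TEN_SET_F1 = (79.10, 79.90, 79.17, 77.20, 78.92, 78.48, 78.18, 80.31, 79.79, 80.00)


class TestConfusion:
    def test_simple_split(self):
        c = confusion([1, 0], [0.9, 0.1])
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)

    def test_threshold_is_inclusive(self):
        """A probability of exactly 0.5 is a positive call."""
        c = confusion([0], [0.5])
        assert c.fp == 1 and c.tn == 0

    def test_all_positives_scored_zero_are_false_negatives(self):
        c = confusion([1] * 7, [0.0] * 7)
        assert c.fn == 7 and c.total == 7

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [0.5])


class TestComputeMetrics:
    def test_hand_computed_counts(self):
        rep = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.ppv == pytest.approx(0.75)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)

    def test_perfect_classifier_scores_six(self):
        rep = compute_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        assert all(getattr(rep, m) == 1.0 for m in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1"))
        assert rep.score == pytest.approx(6.0)

    def test_one_class_test_set_reports_na_not_zero(self):
        # all-positive test set, everything predicted positive: the
        # negative-side ratios are 0/0 and must surface as NA
        rep = compute_metrics(ConfusionCounts(tp=4, fp=0, tn=0, fn=0))
        assert rep.specificity is None and rep.npv is None
        assert rep.score is None
        assert rep.accuracy == pytest.approx(1.0) and rep.sensitivity == pytest.approx(1.0)

    def test_score_is_sum_of_fraction_metrics(self):
        rep = MetricsReport(*(v / 100 for v in NH2_ROW))
        assert rep.score == pytest.approx(5.6930, abs=5e-5)
        rep1 = MetricsReport(*(v / 100 for v in NH1_ROW))
        assert rep1.score == pytest.approx(5.7883, abs=5e-5)

    def test_f1_is_harmonic_mean_of_ppv_and_sensitivity(self):
        c = ConfusionCounts(tp=13, fp=6, tn=20, fn=4)
        rep = compute_metrics(c)
        harm = 2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity)
        assert rep.f1 == pytest.approx(harm)


class TestCurveMetrics:
    def test_perfect_ranking_auc_one(self):
        auc, aupr = curve_metrics([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0 and aupr == 1.0

    def test_constant_scores_auc_half(self):
        auc, _ = curve_metrics([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_undefined(self):
        assert curve_metrics([1, 1], [0.2, 0.9]) == (None, None)


class TestAveraging:
    def test_published_ten_set_averages(self):
        reports = [MetricsReport(accuracy=a / 100, f1=f / 100)
                   for a, f in zip(TEN_SET_ACCURACY, TEN_SET_F1)]
        avg = average_reports(reports)
        assert float(percent_display(avg.accuracy)) == pytest.approx(79.97)
        assert float(percent_display(avg.f1)) == pytest.approx(79.11)

    def test_single_report_is_identity(self):
        rep = MetricsReport(accuracy=0.8, f1=0.7)
        avg = average_reports([rep])
        assert avg.accuracy == pytest.approx(0.8) and avg.f1 == pytest.approx(0.7)

    def test_two_report_mean(self):
        avg = average_reports([MetricsReport(accuracy=0.6), MetricsReport(accuracy=0.8)])
        assert avg.accuracy == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_reports([])

    def test_na_propagates(self):
        avg = average_reports([MetricsReport(accuracy=0.5, npv=None),
                               MetricsReport(accuracy=0.7, npv=0.9)])
        assert avg.npv is None and avg.accuracy == pytest.approx(0.6)


class TestDisplayRounding:
    def test_half_up_percentage(self):
        assert str(percent_display(0.79105)) == "79.11"  # banker's would print 79.10
        assert str(percent_display(0.5)) == "50.00"


class TestEvaluate:
    def test_combines_confusion_and_curves(self, rng):
        labels = rng.integers(0, 2, size=200)
        probs = np.clip(labels * 0.6 + rng.random(200) * 0.4, 0, 1)
        rep = evaluate(labels, probs)
        assert rep.auc is not None and rep.auc > 0.5
        assert rep.score is not None and 0 <= rep.score <= 6
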