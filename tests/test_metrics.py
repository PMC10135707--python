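"""Scalar metrics, ranked metrics, fold aggregation, the confusion-matrix
auditor, and the cohort-comparison statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from pelvistrat.cohort_stats import (
    ContingencyTable2x2,
    fisher_exact_2x2,
    mann_whitney,
    pearson_chi2_2x2,
    t_test_from_summary,
)
from pelvistrat.errors import ConfigurationError
from pelvistrat.metrics import (
    ConfusionMatrix,
    MetricReport,
    aggregate_folds,
    compute_metrics,
    confusion,
    pr_ap,
    roc_auc,
    round_half_away,
    solve_confusion_from_metrics,
)


class TestConfusion:
    def test_perfect_prediction(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_all_positive_prediction(self):
        cm = confusion([1, 1, 1, 1], [1, 0, 1, 0])
        assert cm.fn == 0 and cm.tn == 0 and cm.n == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestComputeMetrics:
    def test_merged_test_set_matrix(self):
        """TP=11 FN=2 TN=9 FP=3 reproduces the merged-model row exactly."""
        rep = compute_metrics(ConfusionMatrix(tp=11, fp=3, tn=9, fn=2)).rounded(3)
        assert (rep.accuracy, rep.precision, rep.specificity, rep.recall, rep.f1) == (
            0.800, 0.786, 0.750, 0.846, 0.815,
        )

    def test_degenerate_matrices(self):
        perfect = compute_metrics(ConfusionMatrix(tp=5, fp=0, tn=0, fn=0))
        assert perfect.accuracy == 1.0 and perfect.recall == 1.0
        assert perfect.specificity is None  # undefined, never 0
        clean = compute_metrics(ConfusionMatrix(tp=3, fp=0, tn=4, fn=0))
        assert clean.accuracy == 1.0 and clean.f1 == 1.0

    def test_metric_identities_hold_on_random_matrices(self, rng):
        for _ in range(300):
            tp, fp, tn, fn = rng.integers(0, 40, 4)
            if tp + fp + tn + fn == 0:
                continue
            cm = ConfusionMatrix(int(tp), int(fp), int(tn), int(fn))
            rep = compute_metrics(cm)
            if rep.precision is not None and rep.recall is not None and rep.precision + rep.recall > 0:
                hm = 2 * rep.precision * rep.recall / (rep.precision + rep.recall)
                assert rep.f1 == pytest.approx(hm, abs=1e-12)
            if rep.recall is not None and rep.specificity is not None:
                pos, neg = tp + fn, tn + fp
                assert rep.accuracy == pytest.approx((rep.recall * pos + rep.specificity * neg) / cm.n, abs=1e-12)


class TestRankedMetrics:
    def test_auc_examples(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[0] == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])[0] == 0.5
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])[0] == pytest.approx(0.75)
        assert roc_auc([0.3, 0.2], [1, 1])[0] is None

    def test_auc_equals_pairwise_win_fraction_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # ties occur
            auc, _, _ = roc_auc(scores, labels)
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_ap_examples_and_rank_invariance(self):
        assert pr_ap([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])[0] == 1.0
        # positives ranked last: precision at the recall steps is 1/3 and 2/4
        ap, _, _ = pr_ap([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert ap == pytest.approx(0.5 * (1 / 3) + 0.5 * (2 / 4), abs=1e-12)
        base = pr_ap([0.1, 0.5, 0.3, 0.9], [0, 1, 0, 1])[0]
        mono = pr_ap([0.01, 0.25, 0.09, 0.81], [0, 1, 0, 1])[0]  # squared scores
        assert base == pytest.approx(mono)
        assert pr_ap([0.3, 0.2], [0, 0])[0] is None


class TestAggregateFolds:
    def test_validation_table_average_row(self):
        accs = (0.850, 0.750, 0.850, 0.850)
        reports = [MetricReport(accuracy=a) for a in accs]
        assert aggregate_folds(reports).rounded(3).accuracy == 0.825

    def test_test_table_average_row(self):
        reports = [MetricReport(accuracy=a) for a in (0.840, 0.880, 0.800, 0.800)]
        assert aggregate_folds(reports).rounded(3).accuracy == 0.830

    def test_identical_reports_average_to_themselves(self):
        rep = MetricReport(accuracy=0.8, precision=0.7, specificity=0.6, recall=0.9, f1=0.787)
        avg = aggregate_folds([rep, rep, rep])
        for name in ("accuracy", "precision", "specificity", "recall", "f1"):
            assert getattr(avg, name) == pytest.approx(getattr(rep, name), abs=1e-12)
        assert avg.auc is None


class TestConfusionAudit:
    def test_printed_merged_metrics_invert_uniquely(self):
        hits = solve_confusion_from_metrics(25, precision=0.786, specificity=0.750, recall=0.846, f1=0.815)
        assert hits == [ConfusionMatrix(tp=11, fp=3, tn=9, fn=2)]

    def test_round_trip_recovers_known_matrix(self):
        cm = ConfusionMatrix(tp=7, fp=2, tn=8, fn=3)
        rep = compute_metrics(cm).rounded(3)
        hits = solve_confusion_from_metrics(20, rep.precision, rep.specificity, rep.recall, rep.f1)
        assert cm in hits

    def test_small_hand_enumerable_case(self):
        hits = solve_confusion_from_metrics(4, precision=1.0, specificity=1.0, recall=0.5, f1=2 / 3)
        assert hits == [ConfusionMatrix(tp=1, fp=0, tn=2, fn=1)]

    def test_rounding_is_half_away_from_zero(self):
        assert round_half_away(0.8155, 3) == 0.816
        assert round_half_away(0.0005, 3) == 0.001


class TestChiSquared:
    def test_closed_form_identity(self, rng):
        """chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on random tables."""
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 60, 4))
            res = pearson_chi2_2x2(ContingencyTable2x2(a, b, c, d))
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res.statistic == pytest.approx(closed, abs=1e-9)

    def test_equal_rows_give_unit_p(self):
        res = pearson_chi2_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ConfigurationError):
            pearson_chi2_2x2(ContingencyTable2x2(0, 0, 5, 5))


class TestTTest:
    def test_hand_evaluated_statistic(self):
        res = t_test_from_summary(1.0, 1.0, 10, 0.0, 1.0, 10)
        assert res.statistic == pytest.approx(1.0 / np.sqrt(2 / 10), abs=1e-3)
        assert res.df == 18

    def test_identical_summaries(self):
        res = t_test_from_summary(5.0, 1.0, 12, 5.0, 1.0, 15)
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestMannWhitney:
    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_identical_samples_give_unit_p(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0] * 5, [1.0, 2.0, 3.0, 4.0] * 5)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_u_statistics_sum_to_product(self, rng):
        x = rng.random(12)
        y = rng.random(9)
        u1 = mann_whitney(x, y).statistic
        u2 = mann_whitney(y, x).statistic
        assert u1 + u2 == pytest.approx(12 * 9)

    def test_fisher_matches_scipy_on_sparse_table(self):
        res = fisher_exact_2x2(ContingencyTable2x2(8, 40, 2, 52))
        assert res.p_value == pytest.approx(sps.fisher_exact([[8, 40], [2, 52]])[1])
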