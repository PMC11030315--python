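"""Confusion counts, per-class metrics, AUC, threshold optimization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from muorpred.ligands import AGONIST, ANTAGONIST
from muorpred.metrics import (
    ConfusionCounts,
    MetricsReport,
    aggregate_runs,
    auc,
    compute_metrics,
    confusion,
    evaluate_scores,
    f1_at_threshold,
    optimize_threshold,
)


class TestConfusion:
    def test_perfect_predictions(self):
        t = [AGONIST] * 5 + [ANTAGONIST] * 5
        c = confusion(t, t)
        assert (c.tag, c.tan, c.fag, c.fan) == (5, 5, 0, 0)

    def test_all_predicted_agonist(self):
        t = [AGONIST] * 3 + [ANTAGONIST] * 2
        p = [AGONIST] * 5
        c = confusion(t, p)
        assert (c.tag, c.fag, c.tan, c.fan) == (3, 2, 0, 0)

    def test_external_validation_case(self):
        """11 of 15 agonists and 7 of 11 antagonists correct."""
        t = [AGONIST] * 15 + [ANTAGONIST] * 11
        p = [AGONIST] * 11 + [ANTAGONIST] * 4 + [ANTAGONIST] * 7 + [AGONIST] * 4
        c = confusion(t, p)
        assert (c.tag, c.tan, c.fag, c.fan) == (11, 7, 4, 4)
        assert c.n_agonists == 15 and c.n_antagonists == 11

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1))
    @settings(max_examples=200, deadline=None)
    def test_tally_equivalence_oracle(self, pairs):
        """Vectorized confusion equals a per-sample brute-force tally."""
        t = [a for a, _ in pairs]
        p = [b for _, b in pairs]
        c = confusion(t, p)
        tally = {"tag": 0, "tan": 0, "fag": 0, "fan": 0}
        for a, b in pairs:
            if a == 0 and b == 0:
                tally["tag"] += 1
            elif a == 1 and b == 1:
                tally["tan"] += 1
            elif a == 1 and b == 0:
                tally["fag"] += 1
            else:
                tally["fan"] += 1
        assert (c.tag, c.tan, c.fag, c.fan) == (
            tally["tag"], tally["tan"], tally["fag"], tally["fan"],
        )


class TestMetrics:
    def test_external_et_column(self):
        rep = compute_metrics(ConfusionCounts(11, 7, 4, 4)).rounded()
        assert rep["recall_ag"] == 73.3
        assert rep["recall_an"] == 63.6
        assert rep["prec_ag"] == 73.3
        assert rep["prec_an"] == 63.6
        assert rep["ba"] == 68.5

    def test_external_mpnn_column(self):
        rep = compute_metrics(ConfusionCounts(12, 9, 2, 3)).rounded()
        assert rep["recall_ag"] == 80.0
        assert rep["recall_an"] == 81.8
        assert rep["prec_ag"] == 85.7
        assert rep["prec_an"] == 75.0
        assert rep["ba"] == 80.9

    def test_perfect_counts_all_hundred(self):
        rep = compute_metrics(ConfusionCounts(7, 7, 0, 0))
        assert all(
            v == 100.0 for k, v in rep.as_dict().items() if k != "auc"
        )

    def test_zero_denominator_reported_absent_not_zero(self):
        rep = compute_metrics(ConfusionCounts(3, 0, 0, 0))  # no antagonists at all
        assert rep.recall_an is None and rep.prec_an is None and rep.ba is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)

    def test_ba_symmetric_under_class_swap(self):
        rep = compute_metrics(ConfusionCounts(11, 7, 4, 4))
        swapped = compute_metrics(ConfusionCounts(7, 11, 4, 4))
        assert rep.ba == pytest.approx(swapped.ba)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_uninformative_scores(self):
        assert auc([0.5] * 6, [0, 1] * 3) == 0.5

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            wins = total = 0.0
            for i in np.flatnonzero(y == 1):
                for j in np.flatnonzero(y == 0):
                    total += 1
                    if s[i] > s[j]:
                        wins += 1
                    elif s[i] == s[j]:
                        wins += 0.5
            assert auc(s, y) == pytest.approx(wins / total)

    def test_monotone_transform_invariance(self):
        s = np.array([0.1, 0.4, 0.35, 0.8])
        y = [0, 1, 0, 1]
        assert auc(s, y) == auc(s**3, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestThreshold:
    def test_separable_scores(self):
        thr = optimize_threshold([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == 0.5
        assert f1_at_threshold(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]), thr) == 1.0

    def test_constant_scores_fall_back_to_half(self):
        assert optimize_threshold([0.3] * 5, [0, 1, 0, 1, 0]) == 0.5

    def test_matches_fine_grid_oracle(self):
        """Achieved F1 equals a 1e-4 grid search over all thresholds that
        nontrivially dichotomize the scores (the all-positive corner below
        the minimum score is not an admissible threshold)."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            s = np.round(rng.random(7), 2)
            y = rng.integers(0, 2, 7)
            if len(np.unique(y)) < 2:
                y[0], y[1] = 0, 1
            thr = optimize_threshold(s, y)
            grid = np.arange(0.0, 1.0001, 1e-4)
            best_grid = max(
                f1_at_threshold(s, y, g) for g in grid if g > s.min()
            )
            assert f1_at_threshold(s, y, thr) == pytest.approx(best_grid, abs=1e-12)

    def test_at_least_as_good_as_default_half(self):
        rng = np.random.default_rng(2)
        s = rng.random(50)
        y = (s + rng.normal(0, 0.3, 50) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        thr = optimize_threshold(s, y)
        assert f1_at_threshold(s, y, thr) >= f1_at_threshold(s, y, 0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimize_threshold([], [])


class TestAggregation:
    def test_identical_reports_zero_sd(self):
        rep = compute_metrics(ConfusionCounts(5, 5, 1, 1))
        agg = aggregate_runs([rep, rep, rep])
        assert agg["ba"]["sd"] == 0.0 and agg["ba"]["n"] == 3

    def test_two_reports_mean_and_sd(self):
        a = MetricsReport(ba=80.0)
        b = MetricsReport(ba=90.0)
        agg = aggregate_runs([a, b])
        assert agg["ba"]["mean"] == 85.0
        assert agg["ba"]["sd"] == pytest.approx(7.0711, abs=1e-3)

    def test_absent_values_skipped_with_count(self):
        a = MetricsReport(ba=80.0, auc=90.0)
        b = MetricsReport(ba=90.0, auc=None)
        agg = aggregate_runs([a, b])
        assert agg["auc"]["n"] == 1 and agg["ba"]["n"] == 2

    def test_ba_linearity_oracle(self):
        """Mean of per-run BA equals BA of mean recalls (linearity)."""
        rng = np.random.default_rng(0)
        reports = [
            MetricsReport(recall_ag=float(a), recall_an=float(b), ba=float((a + b) / 2))
            for a, b in rng.random((10, 2)) * 100
        ]
        agg = aggregate_runs(reports)
        assert agg["ba"]["mean"] == pytest.approx(
            (agg["recall_ag"]["mean"] + agg["recall_an"]["mean"]) / 2
        )

    def test_single_report_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([MetricsReport(ba=1.0)])


def test_evaluate_scores_full_report():
    rng = np.random.default_rng(0)
    y = np.array([0] * 30 + [1] * 10)
    s = np.clip(y * 0.6 + rng.normal(0.2, 0.15, 40), 0, 1)
    rep = evaluate_scores(s, y)
    assert rep.auc is not None and rep.threshold is not None
    assert 0 <= rep.auc <= 100
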