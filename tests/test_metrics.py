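"""Evaluation metrics against brute-force oracles and algebraic identities."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abarec.cohort import MasteryRecord, TreatmentCode
from abarec.exceptions import UndefinedMetricError
from abarec.metrics import (
    ConfusionCounts,
    ap_at_k,
    aggregate_mean,
    cg_at_k,
    classification_metrics,
    commonality,
    confusion_counts,
    dcg_at_k,
    idcg_at_k,
    map_at_k,
    ndcg_at_k,
    p_at_k,
    roc_auc,
    treatment_effectiveness,
)


def pairwise_auc(scores, labels):
    """All-pairs comparison oracle: P(pos > neg) with ties counting 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_enumerated_example(self):
        c = confusion_counts({1, 2}, {2, 3}, {1, 2, 3, 4})
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_perfect_recommendation(self):
        c = confusion_counts({1, 2}, {1, 2}, {1, 2, 3})
        assert c.fp == c.fn == 0

    def test_universe_membership_enforced(self):
        with pytest.raises(UndefinedMetricError):
            confusion_counts({9}, {1}, {1, 2})

    def test_counts_partition_the_universe(self):
        c = confusion_counts({1, 2, 5}, {2, 3}, set(range(10)))
        assert c.total == 10


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            # precision 0.64 / recall 1.0 and 0.90 / 0.96, F1 to two decimals
            (ConfusionCounts(tp=64, fp=36, tn=0, fn=0), 0.78),
            (ConfusionCounts(tp=90, fp=10, tn=0, fn=4), 0.93),
        ],
    )
    def test_f1_matches_published_rounding(self, counts, expected):
        m = classification_metrics(counts)
        assert round(m["f1"], 2) == expected

    def test_accuracy_example(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=1, tn=3, fn=1))
        assert m["accuracy"] == pytest.approx(0.8)

    @given(tp=st.integers(1, 50), fp=st.integers(0, 50), fn=st.integers(0, 50),
           tn=st.integers(0, 50))
    def test_f1_is_harmonic_mean_of_precision_and_recall(self, tp, fp, fn, tn):
        m = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        p, r = m["precision"], m["recall"]
        assert m["f1"] == pytest.approx(2 * p * r / (p + r))

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            classification_metrics(ConfusionCounts(0, 0, 5, 2))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_all_pairs_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                pairwise_auc(scores, labels), abs=1e-12
            )

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        assert roc_auc(scores, labels) == pytest.approx(roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])


class TestPrecisionAtK:
    def test_examples(self):
        assert p_at_k([1, 1, 0, 1, 0], 5) == pytest.approx(0.6)
        assert p_at_k([1, 1, 1], 3) == 1.0
        assert p_at_k([0, 0, 0, 0], 3) == 0.0

    def test_k_zero_rejected(self):
        with pytest.raises(UndefinedMetricError):
            p_at_k([1], 0)


class TestAveragePrecision:
    def test_hand_expanded_example(self):
        # hits at ranks 1 and 3 of 2 relevant: (1/2)(1 + 2/3)
        assert ap_at_k([1, 0, 1], 3, m=2) == pytest.approx(5 / 6)

    def test_single_relevant_ranked_first(self):
        assert ap_at_k([1, 0, 0], 3, m=1) == 1.0

    def test_no_relevant_items_scores_zero(self):
        assert ap_at_k([0, 0, 0], 3, m=0) == 0.0

    def test_truncation_normalizer_keeps_ap_below_one(self):
        # m > k: normalise by k, not m, so a perfect prefix still scores 1
        assert ap_at_k([1, 1, 1], 3, m=10) == pytest.approx(1.0)

    def test_map_is_mean_of_aps(self):
        assert map_at_k([0.5, 1.0]) == pytest.approx(0.75)
        assert map_at_k([0.4, 0.4, 0.4]) == pytest.approx(0.4)

    def test_map_of_empty_user_set_rejected(self):
        with pytest.raises(UndefinedMetricError):
            map_at_k([])


class TestNdcg:
    def test_descending_gains_are_ideal(self):
        assert ndcg_at_k([5.0, 3.0, 1.0, 0.5], 4) == pytest.approx(1.0)

    def test_term_by_term_dcg(self):
        expected = 3 + 2 / math.log2(3) + 3 / 2 + 0 + 1 / math.log2(6)
        assert dcg_at_k([3, 2, 3, 0, 1], 5) == pytest.approx(expected, abs=1e-9)
        assert cg_at_k([3, 2, 3, 0, 1], 5) == 9.0

    def test_all_zero_gains_define_ndcg_zero(self):
        assert ndcg_at_k([0.0, 0.0], 2) == 0.0

    def test_short_lists_are_zero_padded(self):
        assert dcg_at_k([2.0], 3) == pytest.approx(2.0)

    def test_negative_gain_rejected(self):
        with pytest.raises(UndefinedMetricError):
            ndcg_at_k([1.0, -0.5], 2)

    @given(gains=st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=8),
           k=st.integers(1, 8))
    @settings(max_examples=100)
    def test_no_permutation_beats_the_sorted_order(self, gains, k):
        assert dcg_at_k(gains, k) <= idcg_at_k(gains, k) + 1e-9

    def test_matches_sklearn(self):
        from sklearn.metrics import ndcg_score

        rng = np.random.default_rng(2)
        gains = rng.integers(0, 4, 8).astype(float)
        if gains.sum() == 0:
            gains[0] = 1.0
        scores = -np.arange(8.0)  # ranking identical to the given order
        assert ndcg_at_k(gains, 5) == pytest.approx(
            float(ndcg_score([gains], [scores], k=5))
        )


class TestCommonality:
    def test_precision_mode_examples(self):
        truth = {TreatmentCode(2), TreatmentCode(4), TreatmentCode(5), TreatmentCode(7)}
        rec = {TreatmentCode(2), TreatmentCode(4), TreatmentCode(5), TreatmentCode(14)}
        assert commonality(rec, truth) == pytest.approx(75.0)
        assert commonality(truth, truth) == 100.0
        assert commonality({TreatmentCode(9)}, truth) == 0.0

    def test_alternative_modes(self):
        rec, truth = {1, 2}, {2, 3, 4}
        assert commonality(rec, truth, "recall") == pytest.approx(100 / 3)
        assert commonality(rec, truth, "jaccard") == pytest.approx(25.0)

    def test_empty_recommendation_rejected(self):
        with pytest.raises(UndefinedMetricError):
            commonality(set(), {1})

    @given(rec=st.sets(st.integers(0, 20), min_size=1, max_size=10),
           truth=st.sets(st.integers(0, 20), max_size=10))
    def test_precision_mode_is_a_multiple_of_its_grain(self, rec, truth):
        value = commonality(rec, truth)
        grain = 100.0 / len(rec)
        assert value / grain == pytest.approx(round(value / grain))


class TestTreatmentEffectiveness:
    def _records(self):
        t = TreatmentCode
        return [
            MasteryRecord("P1", t(1, 1), True, 10.0, 2),
            MasteryRecord("P1", t(2, 1), True, 12.0, 5),
            MasteryRecord("P1", t(2, 3), False, None, 5),
            MasteryRecord("P1", t(4, 2), True, 20.0, 2),
        ]

    def test_fraction_of_recommended_targets_mastered(self):
        t = TreatmentCode
        rec = [t(1, 1), t(2, 1), t(2, 3), t(5, 1), t(4, 2)]
        assert treatment_effectiveness(rec, self._records(), (1, 6)) == pytest.approx(60.0)

    def test_window_excludes_out_of_range_mastery(self):
        t = TreatmentCode
        assert treatment_effectiveness([t(1, 1)], self._records(), (4, 6)) == 0.0
        assert treatment_effectiveness([t(2, 1)], self._records(), (4, 6)) == 100.0

    def test_domain_counts_when_any_target_mastered(self):
        rec = [TreatmentCode(2), TreatmentCode(9)]
        assert treatment_effectiveness(rec, self._records(), (1, 6)) == pytest.approx(50.0)

    def test_none_mastered_and_empty_recommendation(self):
        assert treatment_effectiveness([TreatmentCode(9, 9)], self._records(), (1, 6)) == 0.0
        with pytest.raises(UndefinedMetricError):
            treatment_effectiveness([], self._records(), (1, 6))


class TestAggregateMean:
    def test_simple_mean_with_n(self):
        assert aggregate_mean([1.0, 2.0, 3.0]) == (2.0, 3)

    def test_fixture_columns_match_published_averages(self):
        from abarec.fixtures import load_fixture_table

        t5 = load_fixture_table("table5")
        mean, n = aggregate_mean(
            t5.numeric_column("Relevant percentage of recommended domain code")
        )
        assert n == 29 and abs(mean - 82.86) <= 0.01

        t9 = load_fixture_table("table9")
        mean, n = aggregate_mean(t9.numeric_column("Sim months 1-3 domain"))
        assert n == 29 and abs(mean - 82.1) <= 0.01

    def test_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            aggregate_mean([])
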