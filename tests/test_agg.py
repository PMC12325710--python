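import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blurscan.agg import (RepeatSet, aggregate_max_ci, aggregate_sets,
                          aggregate_weighted, binarize, confusion_and_metrics,
                          consistency, repeat_sets_from_frame, roc_auc,
                          threshold_at_indeterminate, threshold_curve)
from blurscan.errors import (EmptyInputError, InvalidScoreError, ShapeError,
                             UndefinedAggregateError, UndefinedAUCError,
                             UnreachableTargetError)
from blurscan.net import Prediction


def pred(score: int, ci: float, k: int = 4) -> Prediction:
    probs = np.full(k, (1.0 - ci) / (k - 1))
    probs[score] = ci
    return Prediction(probabilities=probs, score=score, ci=ci)


def repeat_set(scores, cis, label=0):
    return RepeatSet(core_id="c", true_label=label,
                     predictions=[pred(s, c) for s, c in zip(scores, cis)])


class TestAggregateMaxCI:
    def test_max_selection(self):
        rs = repeat_set([1, 2, 1], [0.5, 0.9, 0.7])
        out = aggregate_max_ci(rs)
        assert out.score == 2 and out.ci == pytest.approx(0.9)

    def test_single_repeat_identity(self):
        rs = repeat_set([3], [0.6])
        assert aggregate_max_ci(rs).score == 3

    def test_tie_lowest_repeat_index(self):
        rs = repeat_set([0, 3, 1], [0.8, 0.8, 0.3])
        assert aggregate_max_ci(rs).score == 0

    def test_empty_error(self):
        with pytest.raises(EmptyInputError):
            RepeatSet(core_id="x", predictions=[])


class TestAggregateWeighted:
    def test_unanimous(self):
        assert aggregate_weighted(repeat_set([2, 2, 2], [0.9, 0.2, 0.5])).score == 2

    def test_worked_example(self):
        # (0*0.5 + 1*0.9 + 1*0.8) / 2.2 = 0.7727 -> 1
        out = aggregate_weighted(repeat_set([0, 1, 1], [0.5, 0.9, 0.8]))
        assert out.raw_value == pytest.approx(0.77272727, abs=1e-6)
        assert out.score == 1

    def test_equal_cis_plain_mean(self):
        assert aggregate_weighted(repeat_set([1, 2, 3], [0.7, 0.7, 0.7])).score == 2

    def test_all_zero_cis(self):
        with pytest.raises(UndefinedAggregateError):
            aggregate_weighted(repeat_set([1, 2], [0.0, 0.0]))

    def test_literal_sum_flag(self):
        out = aggregate_weighted(repeat_set([3, 3, 3], [0.9, 0.9, 0.9]),
                                 normalize=False)
        assert out.raw_value == pytest.approx(8.1)
        assert out.score == 3  # clamped to the valid range

    def test_rounding_half_away_from_zero(self):
        out = aggregate_weighted(repeat_set([1, 2], [0.5, 0.5]))
        assert out.raw_value == pytest.approx(1.5)
        assert out.score == 2

    @given(st.lists(st.tuples(st.integers(0, 3),
                              st.floats(0.01, 1.0)), min_size=1, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_score_within_repeat_range(self, items):
        scores = [s for s, _ in items]
        cis = [c for _, c in items]
        out = aggregate_weighted(repeat_set(scores, cis))
        assert min(scores) <= out.score <= max(scores)


class TestConsistency:
    def test_two_of_three(self):
        assert consistency(repeat_set([2, 2, 3], [0.5] * 3)) == pytest.approx(2 / 3)

    def test_unanimous(self):
        assert consistency(repeat_set([1, 1, 1], [0.5] * 3)) == pytest.approx(1.0)

    def test_all_distinct(self):
        assert consistency(repeat_set([0, 1, 2], [0.5] * 3)) == pytest.approx(1 / 3)


class TestThresholdCurve:
    def test_zero_threshold_keeps_all(self):
        curve = threshold_curve([0, 1], [0, 0], [0.5, 0.6],
                                thresholds=np.array([0.0]))
        assert curve.indeterminate_fraction[0] == 0.0
        assert curve.accuracy[0] == pytest.approx(0.5)

    def test_above_max_ci_all_indeterminate(self):
        curve = threshold_curve([0, 1], [0, 1], [0.5, 0.6],
                                thresholds=np.array([0.9]))
        assert curve.indeterminate_fraction[0] == 1.0
        assert np.isnan(curve.accuracy[0])

    def test_accuracy_jumps_at_separating_threshold(self):
        # low-CI predictions all wrong, high-CI all right
        y_true = [0] * 10
        y_pred = [1] * 5 + [0] * 5
        ci = [0.3] * 5 + [0.9] * 5
        curve = threshold_curve(y_true, y_pred, ci,
                                thresholds=np.array([0.0, 0.5, 1.0]))
        assert curve.accuracy[0] == pytest.approx(0.5)
        assert curve.accuracy[1] == pytest.approx(1.0)

    def test_indeterminate_fraction_monotone(self, rng):
        ci = rng.random(50)
        y = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        curve = threshold_curve(y, p, ci)
        assert (np.diff(curve.indeterminate_fraction) >= -1e-12).all()


class TestThresholdAtIndeterminate:
    def test_target_zero(self):
        curve = threshold_curve([0], [0], [0.5])
        assert threshold_at_indeterminate(curve, 0.0) == pytest.approx(0.0)

    def test_fifteen_percent_fixture(self):
        ci = [0.4] * 15 + [0.9] * 85
        y = [0] * 100
        curve = threshold_curve(y, y, ci)
        theta = threshold_at_indeterminate(curve, 0.15)
        assert 0.4 < theta <= 0.42

    def test_unreachable(self):
        curve = threshold_curve([0], [0], [0.5])
        with pytest.raises(UnreachableTargetError):
            threshold_at_indeterminate(curve, 1.01)


class TestBinarize:
    @pytest.mark.parametrize("four,two", [(0, 0), (1, 0), (2, 1), (3, 1)])
    def test_mapping(self, four, two):
        assert binarize(four) == two

    def test_invalid(self):
        with pytest.raises(InvalidScoreError):
            binarize(4)

    def test_commutes_on_unanimous_repeats(self):
        rs4 = repeat_set([3, 3, 3], [0.5, 0.9, 0.7])
        direct = binarize(aggregate_max_ci(rs4).score)
        rs2 = repeat_set([binarize(s) for s in rs4.scores], rs4.cis)
        assert direct == aggregate_max_ci(rs2).score


class TestConfusionAndMetrics:
    def test_perfect_predictions(self):
        cm, metrics = confusion_and_metrics([0, 1, 2, 3], [0, 1, 2, 3], 4)
        assert np.array_equal(cm.counts, np.eye(4, dtype=int))
        assert metrics["accuracy"] == 1.0

    def test_binary_sensitivity_specificity(self):
        # TP=3, FN=1, TN=5, FP=1
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        y_pred = [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]
        _, metrics = confusion_and_metrics(y_true, y_pred, 2)
        assert metrics["sensitivity"] == pytest.approx(0.75)
        assert metrics["specificity"] == pytest.approx(5 / 6, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            confusion_and_metrics([0, 1], [0], 2)

    def test_total_counts(self):
        cm, _ = confusion_and_metrics([0, 0, 1], [1, 0, 1], 2)
        assert cm.total == 3


class TestRocAuc:
    def test_perfect_separation(self):
        probs = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        _, _, auc = roc_auc(probs, labels)
        assert auc == pytest.approx(1.0)

    def test_null_simulation(self):
        rng = np.random.default_rng(7)
        probs = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        _, _, auc = roc_auc(probs, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_all_equal_probabilities(self):
        _, _, auc = roc_auc([0.5] * 10, [0, 1] * 5)
        assert auc == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_against_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        probs = rng.random(200)
        labels = rng.integers(0, 2, 200)
        _, _, auc = roc_auc(probs, labels)
        assert auc == pytest.approx(roc_auc_score(labels, probs), abs=1e-12)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, data):
        n = data.draw(st.integers(4, 30))
        # 3-decimal grid keeps tied values tied (and distinct values
        # distinct) through the float transform below
        probs = np.array(data.draw(st.lists(
            st.floats(0.01, 0.99), min_size=n, max_size=n))).round(3)
        labels = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)))
        if labels.min() == labels.max():
            return
        _, _, auc1 = roc_auc(probs, labels)
        _, _, auc2 = roc_auc(np.exp(3 * probs), labels)  # strictly monotone
        assert auc1 == pytest.approx(auc2, abs=1e-12)


class TestAggregateSets:
    def test_methods_shapes(self):
        sets = [repeat_set([0, 1, 1], [0.5, 0.9, 0.8], label=1),
                repeat_set([2, 2, 3], [0.7, 0.6, 0.9], label=2)]
        assert len(aggregate_sets(sets, "all")) == 6
        assert len(aggregate_sets(sets, "maxci")) == 2
        df = aggregate_sets(sets, "weighted")
        # (2*0.7 + 2*0.6 + 3*0.9) / 2.2 = 2.41 -> 2
        assert list(df["score"]) == [1, 2]

    def test_frame_round_trip(self):
        import pandas as pd
        preds = pd.DataFrame({
            "core_id": ["a", "a", "b"],
            "repeat_index": [1, 2, 1],
            "score": [1, 2, 0],
            "ci": [0.6, 0.9, 0.5],
            "p0": [0.1, 0.0, 0.5], "p1": [0.6, 0.1, 0.3],
            "p2": [0.2, 0.9, 0.1], "p3": [0.1, 0.0, 0.1]})
        labels = pd.DataFrame({"core_id": ["a", "b"], "her2_score": [2, 0]})
        sets = repeat_sets_from_frame(preds, labels)
        assert len(sets) == 2
        by_id = {rs.core_id: rs for rs in sets}
        assert by_id["a"].true_label == 2
        assert aggregate_max_ci(by_id["a"]).score == 2
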