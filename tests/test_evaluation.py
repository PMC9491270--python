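"""Per-class metrics, report layout, cross-domain harness."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from deplex.evaluation import (
    ConfusionCounts,
    confusion_counts,
    cross_domain_evaluate,
    evaluate,
    precision_recall_f1,
    report_from_predictions,
)
from deplex.features import FeatureMatrix, Vocabulary, encode_posts
from deplex.models import ModelConfig, TrainedClassifier, build_classifier, train_classifier


class TestConfusionCounts:
    def test_perfect_agreement(self):
        c = confusion_counts([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_constant_positive_predictions(self):
        c = confusion_counts([1, 0], [1, 1])
        assert (c.tp, c.fp) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_counts([1, 0], [1])

    def test_random_pair_matches_loop_tally_and_sklearn(self):
        rng = np.random.default_rng(8)
        y_true = rng.integers(0, 2, 1000)
        y_pred = rng.integers(0, 2, 1000)
        c = confusion_counts(y_true, y_pred)
        tally = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
        for t, p in zip(y_true, y_pred):
            key = ("t" if t == p else "f") + ("p" if p == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.fn, c.tn) == (tally["tp"], tally["fp"], tally["fn"], tally["tn"])
        tn, fp, fn, tp = confusion_matrix(y_true, y_pred).ravel()
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)


class TestPrecisionRecallF1:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            (ConfusionCounts(5, 0, 0, 0), (1.0, 1.0, 1.0)),
            (ConfusionCounts(3, 1, 1, 5), (0.75, 0.75, 0.75)),
            (ConfusionCounts(0, 0, 5, 5), (0.0, 0.0, 0.0)),  # 0/0 -> 0
            (ConfusionCounts(2, 2, 0, 0), (0.5, 1.0, 2 / 3)),
            (ConfusionCounts(0, 0, 0, 10), (0.0, 0.0, 0.0)),
        ],
    )
    def test_hand_computed_values(self, counts, expected):
        assert precision_recall_f1(counts) == pytest.approx(expected)

    def test_agrees_with_sklearn_on_random_labels(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 2, 500)
        y_pred = rng.integers(0, 2, 500)
        p, r, f1 = precision_recall_f1(confusion_counts(y_true, y_pred))
        sp, sr, sf, _ = precision_recall_fscore_support(
            y_true, y_pred, average="binary", zero_division=0
        )
        assert (p, r, f1) == pytest.approx((sp, sr, sf))


class TestEvalReport:
    def test_constant_positive_on_balanced_data(self):
        y_true = [0] * 50 + [1] * 50
        report = report_from_predictions(y_true, [1] * 100)
        assert report.accuracy == pytest.approx(0.5)
        pos = report.per_class[1]
        assert (pos.precision, pos.recall) == (0.5, 1.0)
        assert pos.f1 == pytest.approx(0.6667, abs=5e-5)
        neg = report.per_class[0]
        assert (neg.precision, neg.recall, neg.f1) == (0.0, 0.0, 0.0)

    def test_internal_consistency_with_own_counts(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 2, 300)
        y_pred = rng.integers(0, 2, 300)
        report = report_from_predictions(y_true, y_pred)
        c = report.counts
        assert c.n == report.n
        assert report.per_class[1].precision == pytest.approx(
            precision_recall_f1(c)[0]
        )
        assert report.accuracy == pytest.approx((c.tp + c.tn) / c.n)

    def test_support_weighted_recalls_reproduce_accuracy(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 2, 400)
        y_pred = rng.integers(0, 2, 400)
        report = report_from_predictions(y_true, y_pred)
        n1 = int(np.sum(y_true))
        n0 = 400 - n1
        weighted = (n0 * report.per_class[0].recall + n1 * report.per_class[1].recall) / 400
        assert weighted == pytest.approx(report.accuracy)

    def test_swapping_positive_class_swaps_rows_keeps_accuracy(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        a = report_from_predictions(y_true, y_pred)
        b = report_from_predictions(1 - y_true, 1 - y_pred)
        assert a.accuracy == b.accuracy
        for cls in (0, 1):
            assert a.per_class[cls] == b.per_class[1 - cls]

    def test_table_layout_has_both_label_rows(self):
        report = report_from_predictions([0, 1], [0, 1])
        table = report.to_table()
        assert "non-depression" in table and "depression" in table
        assert "1.0000" in table

    def test_empty_evaluation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            report_from_predictions([], [])


@pytest.fixture(scope="module")
def separable_trained():
    rng = np.random.default_rng(0)
    tokens = [[f"t{rng.integers(2, 20)}" for _ in range(6)] for _ in range(80)]
    y = np.arange(80) % 2
    for i in np.flatnonzero(y):
        tokens[i][0] = "marker"
    vocab = Vocabulary([f"t{i}" for i in range(2, 20)] + ["marker"])
    cfg = ModelConfig.for_family("cnn", max_len=8, epochs=20, seed=0, dropout_rate=0.0)
    fm = encode_posts(tokens, vocab, cfg.max_len, labels=y)
    trained = train_classifier(build_classifier(cfg, len(vocab)), fm, None, cfg, vocabulary=vocab)
    return trained, tokens, y, fm


class TestEvaluate:
    def test_perfect_classifier_scores_one(self, separable_trained):
        trained, _, _, fm = separable_trained
        report = evaluate(trained, fm)
        assert report.accuracy == 1.0
        for cls in (0, 1):
            m = report.per_class[cls]
            assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_cross_domain_on_identical_corpus_matches_in_domain(self, separable_trained):
        trained, tokens, y, fm = separable_trained
        in_report = evaluate(trained, fm)
        cross = cross_domain_evaluate(trained, tokens, y)
        assert cross.domain == "cross_domain"
        assert cross.accuracy == in_report.accuracy
        assert cross.per_class[1] == in_report.per_class[1]

    def test_vocabulary_shift_does_not_beat_in_domain(self, separable_trained):
        trained, tokens, y, fm = separable_trained
        rng = np.random.default_rng(9)
        shifted = [
            [t if (t == "marker" or rng.random() > 0.5) else "unseen" for t in toks]
            for toks in tokens
        ]
        cross = cross_domain_evaluate(trained, shifted, y)
        assert cross.per_class[1].f1 <= evaluate(trained, fm).per_class[1].f1

    def test_empty_target_corpus_rejected(self, separable_trained):
        trained, *_ = separable_trained
        with pytest.raises(ValueError, match="empty"):
            cross_domain_evaluate(trained, [], [])

    def test_missing_vocabulary_rejected(self, separable_trained):
        trained, tokens, y, _ = separable_trained
        stripped = TrainedClassifier(trained.classifier, trained.config, vocabulary=None)
        with pytest.raises(ValueError, match="vocabulary"):
            cross_domain_evaluate(stripped, tokens, y)
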