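"""Confusion-matrix metric suite vs hand counts and scikit-learn."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystodx.metrics import ConfusionMatrix, compute_metrics, confusion_matrix


class TestConfusionMatrix:
    def test_perfect_diagonal(self):
        cm = confusion_matrix(("A", "B", "A"), ("A", "B", "A"), ("A", "B"))
        assert cm.counts.tolist() == [[2, 0], [0, 1]]

    def test_hand_count(self):
        cm = confusion_matrix(("A", "A", "B"), ("B", "A", "B"), ("A", "B"))
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix((), (), ("A", "B"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix(("A",), ("A", "B"), ("A", "B"))

    def test_unknown_label(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix(("A", "C"), ("A", "A"), ("A", "B"))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 5), st.integers(1, 200), st.integers(0, 10_000))
    def test_matches_pairwise_counting_oracle(self, n_classes, n, seed):
        rng = np.random.default_rng(seed)
        classes = tuple(f"C{i}" for i in range(n_classes))
        truth = [classes[i] for i in rng.integers(0, n_classes, n)]
        pred = [classes[i] for i in rng.integers(0, n_classes, n)]
        cm = confusion_matrix(truth, pred, classes)
        for i, ci in enumerate(classes):
            for j, cj in enumerate(classes):
                brute = sum(1 for t, p in zip(truth, pred) if t == ci and p == cj)
                assert cm.counts[i, j] == brute


class TestComputeMetrics:
    def test_binary_hand_example(self):
        # TP=5, FN=1, FP=2, TN=4 for the positive class
        cm = ConfusionMatrix(np.array([[5, 1], [2, 4]]), ("pos", "neg"))
        rep = compute_metrics(cm)
        assert rep.accuracy == pytest.approx(0.75)
        assert rep.error == pytest.approx(0.25)
        assert rep.per_class_precision[0] == pytest.approx(5 / 7)
        assert rep.per_class_recall[0] == pytest.approx(5 / 6)
        p, r = 5 / 7, 5 / 6
        assert 2 * p * r / (p + r) == pytest.approx(0.7692, abs=1e-4)

    def test_three_class_hand_example(self):
        cm = ConfusionMatrix(np.array([[2, 1, 0], [0, 2, 0], [0, 0, 2]]),
                             ("a", "b", "c"))
        rep = compute_metrics(cm)
        assert rep.accuracy == pytest.approx(6 / 7)
        assert rep.macro_precision == pytest.approx((1 + 2 / 3 + 1) / 3)
        assert rep.macro_recall == pytest.approx((2 / 3 + 1 + 1) / 3)

    def test_perfect_diagonal(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]), ("a", "b", "c"))
        rep = compute_metrics(cm)
        assert rep.accuracy == 1.0 and rep.error == 0.0
        assert np.all(rep.per_class_precision == 1.0)
        assert np.all(rep.per_class_recall == 1.0)

    def test_zero_denominator_class_reported_as_zero(self):
        # class b never predicted and never true -> precision = recall = 0
        cm = ConfusionMatrix(np.array([[3, 0], [0, 0]]), ("a", "b"))
        rep = compute_metrics(cm)
        assert rep.per_class_precision[1] == 0.0
        assert rep.per_class_recall[1] == 0.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix(np.zeros((2, 2), int), ("a", "b")))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 5), st.integers(2, 200), st.integers(0, 10_000))
    def test_agrees_with_sklearn(self, n_classes, n, seed):
        from sklearn.metrics import accuracy_score, precision_score, recall_score

        rng = np.random.default_rng(seed)
        classes = tuple(f"C{i}" for i in range(n_classes))
        truth = [classes[i] for i in rng.integers(0, n_classes, n)]
        pred = [classes[i] for i in rng.integers(0, n_classes, n)]
        rep = compute_metrics(confusion_matrix(truth, pred, classes))
        assert rep.accuracy == pytest.approx(accuracy_score(truth, pred))
        assert rep.macro_precision == pytest.approx(
            precision_score(truth, pred, labels=list(classes), average="macro",
                            zero_division=0))
        assert rep.macro_recall == pytest.approx(
            recall_score(truth, pred, labels=list(classes), average="macro",
                         zero_division=0))
        assert rep.micro_precision == pytest.approx(
            precision_score(truth, pred, labels=list(classes), average="micro",
                            zero_division=0))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(2, 4), st.integers(2, 100), st.integers(0, 10_000))
    def test_single_label_identity_and_error(self, n_classes, n, seed):
        rng = np.random.default_rng(seed)
        classes = tuple(f"C{i}" for i in range(n_classes))
        truth = [classes[i] for i in rng.integers(0, n_classes, n)]
        pred = [classes[i] for i in rng.integers(0, n_classes, n)]
        rep = compute_metrics(confusion_matrix(truth, pred, classes))
        assert rep.micro_precision == pytest.approx(rep.accuracy)
        assert rep.micro_recall == pytest.approx(rep.accuracy)
        assert rep.error == pytest.approx(1.0 - rep.accuracy)

    def test_class_permutation_invariance(self):
        rng = np.random.default_rng(7)
        classes = ("a", "b", "c")
        truth = [classes[i] for i in rng.integers(0, 3, 60)]
        pred = [classes[i] for i in rng.integers(0, 3, 60)]
        rep1 = compute_metrics(confusion_matrix(truth, pred, classes))
        rep2 = compute_metrics(confusion_matrix(truth, pred, ("c", "a", "b")))
        assert rep1.accuracy == pytest.approx(rep2.accuracy)
        assert rep1.macro_precision == pytest.approx(rep2.macro_precision)
        assert rep1.micro_recall == pytest.approx(rep2.micro_recall)
        assert rep1.f1 == pytest.approx(rep2.f1)
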