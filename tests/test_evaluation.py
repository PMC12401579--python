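"""Nine test metrics vs brute-force formulas; hierarchical metric orderings."""

import numpy as np
import pytest

from hallmarkgraph import evaluation as ev


def brute_force_metrics(cm: np.ndarray) -> dict:
    """Independent metric computation straight from a confusion matrix."""
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    row = cm.sum(axis=1).astype(float)  # true counts
    col = cm.sum(axis=0).astype(float)  # predicted counts
    present = row > 0
    recall = np.divide(tp, row, out=np.zeros_like(tp), where=row > 0)
    precision = np.divide(tp, col, out=np.zeros_like(tp), where=col > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(
            precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0
        )
    return {
        "accuracy": tp.sum() / n,
        "balanced_accuracy": recall[present].mean(),
        "weighted_f1": (f1 * row).sum() / n,
        "micro_precision": tp.sum() / n,
        "micro_recall": tp.sum() / n,
        "micro_f1": tp.sum() / n,
        "macro_precision": precision.mean(),
        "macro_recall": recall.mean(),
        "macro_f1": f1.mean(),
    }


def labels_from_confusion(cm: np.ndarray):
    y_true, y_pred = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            y_true += [i] * cm[i, j]
            y_pred += [j] * cm[i, j]
    return np.asarray(y_true), np.asarray(y_pred)


class TestComputeMetrics:
    def test_perfect_predictions_give_all_ones(self):
        y = np.array([0, 1, 2, 2, 1])
        probs = np.eye(3)[y]
        report = ev.compute_metrics(y, y, probs, vocabulary=[0, 1, 2])
        for name, value in report.as_dict().items():
            assert value == pytest.approx(1.0), name

    def test_hand_computed_two_class_fixture(self):
        # confusion [[2,1],[1,6]]: accuracy 0.8, balanced (2/3 + 6/7)/2
        y_true, y_pred = labels_from_confusion(np.array([[2, 1], [1, 6]]))
        report = ev.compute_metrics(y_true, y_pred)
        assert report.accuracy == pytest.approx(0.8)
        assert report.balanced_accuracy == pytest.approx(0.7619047619, abs=1e-9)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_confusions(self, seed):
        rng = np.random.default_rng(seed)
        c = int(rng.integers(2, 8))
        cm = rng.integers(0, 9, size=(c, c))
        cm[0, 0] += 1  # at least one sample
        y_true, y_pred = labels_from_confusion(cm)
        report = ev.compute_metrics(y_true, y_pred, vocabulary=list(range(c)))
        expected = brute_force_metrics(cm)
        for name, value in expected.items():
            assert report.as_dict()[name] == pytest.approx(value, abs=1e-9), name

    def test_micro_metrics_equal_accuracy(self):
        rng = np.random.default_rng(1)
        y_true = rng.integers(0, 4, size=50)
        y_pred = rng.integers(0, 4, size=50)
        r = ev.compute_metrics(y_true, y_pred)
        assert r.micro_precision == pytest.approx(r.accuracy, abs=1e-12)
        assert r.micro_recall == pytest.approx(r.accuracy, abs=1e-12)
        assert r.micro_f1 == pytest.approx(r.accuracy, abs=1e-12)

    def test_metrics_invariant_under_label_permutation(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 3, size=60)
        y_pred = rng.integers(0, 3, size=60)
        probs = rng.dirichlet(np.ones(3), size=60)
        base = ev.compute_metrics(y_true, y_pred, probs, vocabulary=[0, 1, 2])
        perm = np.array([2, 0, 1])
        permuted = ev.compute_metrics(
            perm[y_true], perm[y_pred], probs[:, np.argsort(perm)],
            vocabulary=[0, 1, 2],
        )
        for name, value in base.as_dict().items():
            assert permuted.as_dict()[name] == pytest.approx(value, abs=1e-9), name

    def test_absent_class_excluded_from_macro_auroc_with_warning(self):
        y_true = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1, 0.0], [0.8, 0.2, 0.0],
                          [0.1, 0.9, 0.0], [0.2, 0.8, 0.0]])
        with pytest.warns(UserWarning, match="no positives"):
            report = ev.compute_metrics(y_true, y_true, probs, vocabulary=[0, 1, 2])
        assert report.macro_auroc == pytest.approx(1.0)

    def test_single_positive_ranked_top_gives_auroc_one(self):
        y_true = np.array([1, 0, 0, 0])
        probs = np.array([[0.1, 0.9], [0.8, 0.2], [0.7, 0.3], [0.6, 0.4]])
        report = ev.compute_metrics(y_true, y_true, probs, vocabulary=[0, 1])
        assert report.macro_auroc == pytest.approx(1.0)


class TestCurves:
    def test_perfect_separation_curve_area(self):
        y_true = np.array([0, 0, 1, 1])
        probs = np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]])
        curves = ev.roc_prc_curves(y_true, probs, vocabulary=[0, 1])
        assert curves[1]["auroc"] == pytest.approx(1.0)
        fpr, tpr = curves[1]["roc"]
        assert (np.isclose(fpr, 0.0) & np.isclose(tpr, 1.0)).any()

    def test_curve_areas_match_metric_report(self):
        rng = np.random.default_rng(3)
        y_true = rng.integers(0, 3, size=80)
        probs = rng.dirichlet(np.ones(3), size=80)
        curves = ev.roc_prc_curves(y_true, probs, vocabulary=[0, 1, 2])
        report = ev.compute_metrics(y_true, probs.argmax(axis=1), probs,
                                    vocabulary=[0, 1, 2])
        assert curves["macro"]["auroc"] == pytest.approx(report.macro_auroc, abs=1e-9)
        assert curves["macro"]["auprc"] == pytest.approx(report.macro_auprc, abs=1e-9)

    def test_random_scores_give_chance_level_macro_auroc(self):
        rng = np.random.default_rng(4)
        n = 10000
        y_true = rng.integers(0, 2, size=n)
        probs = rng.dirichlet(np.ones(2), size=n)
        curves = ev.roc_prc_curves(y_true, probs, vocabulary=[0, 1])
        assert curves["macro"]["auroc"] == pytest.approx(0.5, abs=0.02)


def hierarchy_fixture():
    truth = {
        "a": ("L1", "L2", "L3"),
        "b": ("L1", "L2", "L3"),
        "c": ("L1", "L2"),
        "d": ("L1",),
    }
    predictions = {
        1: {"a": "L1", "b": "L1", "c": "X", "d": "L1"},
        2: {"a": "L2", "b": "X", "c": "L2"},
        3: {"a": "L3", "b": "L3"},
    }
    return predictions, truth


class TestHierarchicalMetrics:
    def test_separate_accuracy_denominators(self):
        predictions, truth = hierarchy_fixture()
        sep = ev.separate_accuracy(predictions, truth)
        assert sep[1] == pytest.approx(3 / 4)
        assert sep[2] == pytest.approx(2 / 3)
        assert sep[3] == pytest.approx(1.0)

    def test_combined_requires_correct_prefix(self):
        predictions, truth = hierarchy_fixture()
        comb = ev.combined_accuracy(predictions, truth)
        # level 2: a correct-correct; b correct-wrong; c wrong-correct
        assert comb[2] == pytest.approx(1 / 3)
        # level 3: only a has the whole prefix right
        assert comb[3] == pytest.approx(1 / 2)

    def test_sample_level_requires_entire_path(self):
        predictions, truth = hierarchy_fixture()
        # a fully correct; b wrong at 2; c wrong at 1; d correct at its only tier
        assert ev.sample_level_accuracy(predictions, truth) == pytest.approx(2 / 4)

    @pytest.mark.parametrize("seed", range(5))
    def test_ordering_combined_le_separate_and_sample_le_combined(self, seed):
        rng = np.random.default_rng(seed)
        depth = 4
        truth, predictions = {}, {k: {} for k in range(1, depth + 1)}
        for i in range(200):
            sid = f"s{i}"
            d = int(rng.integers(1, depth + 1))
            truth[sid] = tuple(f"T{k}" for k in range(d))
            for k in range(1, d + 1):
                predictions[k][sid] = (
                    f"T{k-1}" if rng.random() > 0.3 else "WRONG"
                )
        sep = ev.separate_accuracy(predictions, truth)
        comb = ev.combined_accuracy(predictions, truth)
        for k in comb:
            assert comb[k] <= sep[k] + 1e-12
        max_depth = max(comb)
        full = {s: t for s, t in truth.items() if len(t) == max_depth}
        sample = ev.sample_level_accuracy(predictions, full)
        assert sample <= comb[max_depth] + 1e-12

    def test_combined_matches_product_law_for_independent_errors(self):
        # independent per-level error rates: chained accuracy at level k is
        # the product of the per-level separate accuracies
        rng = np.random.default_rng(99)
        n, rates = 5000, (0.9, 0.8, 0.7)
        truth, predictions = {}, {1: {}, 2: {}, 3: {}}
        for i in range(n):
            sid = f"s{i}"
            truth[sid] = ("A", "B", "C")
            for k, rate in enumerate(rates, start=1):
                correct = rng.random() < rate
                predictions[k][sid] = truth[sid][k - 1] if correct else "W"
        comb = ev.combined_accuracy(predictions, truth)
        expected = 1.0
        sep = ev.separate_accuracy(predictions, truth)
        for k, rate in enumerate(rates, start=1):
            expected *= sep[k]
            # Monte-Carlo error ~ 3/sqrt(n)
            assert comb[k] == pytest.approx(expected, abs=3 / np.sqrt(n))
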