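import numpy as np
import pytest

from ddievent.evaluate import compute_metrics, kfold_split, per_event_scores, run_cv
from ddievent.io_model import EventEdgeList, ValidationError


# ---------------------------------------------------------------------------
# independent metric oracle: confusion-matrix arithmetic + rank statistics,
# no scikit-learn involved
# ---------------------------------------------------------------------------

def oracle_macro_scores(y_true, y_pred, classes):
    precs, recs, f1s = [], [], []
    for c in classes:
        tp = np.sum((y_pred == c) & (y_true == c))
        fp = np.sum((y_pred == c) & (y_true != c))
        fn = np.sum((y_pred != c) & (y_true == c))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        precs.append(p)
        recs.append(r)
        f1s.append(2 * p * r / (p + r) if p + r else 0.0)
    return np.mean(precs), np.mean(recs), np.mean(f1s)


def oracle_micro_f1(y_true, y_pred):
    # pooled over classes: every error is one FP and one FN, so micro
    # precision = recall = f1 = accuracy for single-label predictions
    classes = np.unique(np.concatenate([y_true, y_pred]))
    tp = sum(np.sum((y_pred == c) & (y_true == c)) for c in classes)
    fp = sum(np.sum((y_pred == c) & (y_true != c)) for c in classes)
    fn = sum(np.sum((y_pred != c) & (y_true == c)) for c in classes)
    # single-division form keeps the accuracy identity exact in floats
    return 2 * tp / (2 * tp + fp + fn)


def oracle_auc(y_bin, scores):
    """Mann-Whitney with average ranks (ties on the ROC diagonal)."""
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and sorted_scores[j] == sorted_scores[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n_pos = y_bin.sum()
    n_neg = len(y_bin) - n_pos
    return (ranks[y_bin == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def oracle_average_precision(y_bin, scores):
    order = np.argsort(-scores, kind="mergesort")
    y = y_bin[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate at the last index of each distinct score (threshold)
    last = np.flatnonzero(np.diff(s, append=np.nan) != 0)
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / y_bin.sum()
    prev_r = 0.0
    ap = 0.0
    for p, r in zip(precision, recall):
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def random_instance(rng, n=40, n_classes=4):
    y = rng.integers(0, n_classes, size=n)
    # make sure every class appears so the oracle scope matches
    y[:n_classes] = np.arange(n_classes)
    probs = rng.random((n, n_classes))
    probs /= probs.sum(axis=1, keepdims=True)
    return y, probs


class TestComputeMetrics:
    def test_hand_computed_example(self):
        # y=[0,1,1] vs argmax [0,1,0]: 2 of 3 correct
        probs = np.array([[0.9, 0.1], [0.2, 0.8], [0.7, 0.3]])
        m = compute_metrics(np.array([0, 1, 1]), probs)
        assert m["accuracy"] == pytest.approx(2 / 3)
        assert oracle_micro_f1(np.array([0, 1, 1]), probs.argmax(axis=1)) == pytest.approx(2 / 3)

    def test_perfect_probabilities(self):
        y = np.array([0, 1, 2, 1, 0])
        probs = np.zeros((5, 3))
        probs[np.arange(5), y] = 1.0
        m = compute_metrics(y, probs)
        for name in ("accuracy", "micro_aupr", "micro_auc", "macro_f1",
                     "macro_precision", "macro_recall"):
            assert m[name] == pytest.approx(1.0)

    def test_uniform_probs_balanced_classes_chance_auc(self):
        y = np.array([0, 1] * 10)
        probs = np.full((20, 2), 0.5)
        m = compute_metrics(y, probs)
        assert m["micro_auc"] == pytest.approx(0.5, abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(np.array([0, 1]), np.full((3, 2), 0.5))

    def test_agrees_with_independent_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y, probs = random_instance(rng)
            m = compute_metrics(y, probs)
            y_pred = probs.argmax(axis=1)
            classes = np.unique(y)
            mp, mr, mf = oracle_macro_scores(y, y_pred, classes)
            assert m["macro_precision"] == pytest.approx(mp, abs=1e-9)
            assert m["macro_recall"] == pytest.approx(mr, abs=1e-9)
            assert m["macro_f1"] == pytest.approx(mf, abs=1e-9)
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(y)), y] = 1
            assert m["micro_auc"] == pytest.approx(
                oracle_auc(onehot.ravel(), probs.ravel()), abs=1e-9
            )
            assert m["micro_aupr"] == pytest.approx(
                oracle_average_precision(onehot.ravel(), probs.ravel()), abs=1e-9
            )

    def test_accuracy_equals_micro_f1_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y, probs = random_instance(rng)
            m = compute_metrics(y, probs)
            assert m["accuracy"] == oracle_micro_f1(y, probs.argmax(axis=1))


class TestKFold:
    def make_edges(self, labels):
        from itertools import combinations

        pairs = list(combinations(range(len(labels) + 1), 2))[: len(labels)]
        edges = tuple((i, j, int(r)) for (i, j), r in zip(pairs, labels))
        return EventEdgeList(edges, int(max(labels)) + 1)

    def test_partition_into_equal_folds(self):
        edges = self.make_edges([0] * 10)
        folds, train_only = kfold_split(edges, 5, seed=0)
        tests = [set(te.tolist()) for _, te in folds]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        assert train_only.size == 0

    def test_rare_event_stays_in_training(self):
        edges = self.make_edges([0] * 10 + [1] * 3)
        folds, train_only = kfold_split(edges, 5, seed=0)
        rare = {10, 11, 12}
        assert set(train_only.tolist()) == rare
        for train, test in folds:
            assert rare.isdisjoint(test.tolist())
            assert rare.issubset(train.tolist())

    def test_test_sets_disjoint(self):
        edges = self.make_edges([0] * 12 + [1] * 9)
        folds, _ = kfold_split(edges, 3, seed=1)
        seen = []
        for _, test in folds:
            seen.extend(test.tolist())
        assert len(seen) == len(set(seen))

    def test_deterministic_under_seed(self):
        edges = self.make_edges([0] * 20)
        f1, _ = kfold_split(edges, 4, seed=9)
        f2, _ = kfold_split(edges, 4, seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_k_larger_than_edges_rejected(self):
        edges = self.make_edges([0, 0])
        with pytest.raises(ValidationError):
            kfold_split(edges, 5, seed=0)


class TestRunCV:
    def test_report_structure_and_aggregates(self, tiny_dataset, tiny_similarities,
                                             fast_embed_params, fast_predictor_config):
        _, _, edges, _, _ = tiny_dataset
        rep = run_cv(edges, tiny_similarities[:1], fast_embed_params,
                     fast_predictor_config, k=5, mode="transductive", seed=0)
        assert rep.mode == "transductive"
        assert len(rep.fold_metrics) == 5
        agg = rep.aggregate
        for name, stats in agg.items():
            assert stats["min"] <= stats["mean"] <= stats["max"]
            assert 0.0 <= stats["min"] and stats["max"] <= 1.0
        assert set(rep.per_event) <= set(range(edges.n_events))

    def test_unknown_mode_rejected(self, tiny_dataset, tiny_similarities,
                                   fast_embed_params, fast_predictor_config):
        _, _, edges, _, _ = tiny_dataset
        with pytest.raises(ValidationError):
            run_cv(edges, tiny_similarities, fast_embed_params,
                   fast_predictor_config, mode="bogus")

    def test_per_event_scores_shape(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 3, size=60)
        probs = rng.random((60, 3))
        probs /= probs.sum(axis=1, keepdims=True)
        pe = per_event_scores(y, probs)
        assert set(pe) == set(np.unique(y).tolist())
        for stats in pe.values():
            assert {"auc", "f1", "n"} <= set(stats)
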