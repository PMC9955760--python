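"""Pivot split, training loop and evaluation metrics."""

import numpy as np
import pytest
from scipy.stats import rankdata

from temporalign import (LinkPredictor, StaticEmbeddingSeries, TemporalEdge,
                         TemporalGraph, TrainConfig, aupr_score, auroc_score,
                         bce_loss, confusion_report, degree_product_auroc,
                         evaluate, pair_feature, temporal_split, train)


def mann_whitney_auc(labels, scores):
    """Independent oracle: tie-averaged rank statistic U / (n_pos * n_neg)."""
    labels = np.asarray(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    U = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2
    return U / (n_pos * n_neg)


def ten_edge_graph():
    edges = [TemporalEdge(i, i + 1, float(t + 1))
             for t, i in enumerate(range(0, 10))]
    # 10 distinct pairs over 11 nodes, times 1..10
    return TemporalGraph(edges)


class TestTemporalSplit:
    def test_ten_edge_counts(self):
        split = temporal_split(ten_edge_graph(), pivot_fraction=0.8, seed=0)
        assert len(split.train_pos) == 8
        assert len(split.test_pos) == 2
        assert len(split.train_neg) == 8
        assert len(split.test_neg) == 2

    def test_buckets_disjoint_and_valid(self, sbm_graph):
        split = temporal_split(sbm_graph, seed=1)
        ever = set()
        for e in sbm_graph.edges:
            i, j = sbm_graph.nodes[e.source], sbm_graph.nodes[e.target]
            ever.add((min(i, j), max(i, j)))
        first_by_pair = {}
        for e in sbm_graph.edges:
            i, j = sorted((sbm_graph.nodes[e.source],
                           sbm_graph.nodes[e.target]))
            first_by_pair[(i, j)] = min(first_by_pair.get((i, j), np.inf),
                                        e.time)
        assert not set(split.test_neg) & ever          # never connected
        for p in split.train_neg:                      # unconnected at pivot
            assert first_by_pair.get(p, np.inf) > split.pivot_time

    def test_complete_graph_has_no_negatives(self):
        edges = [TemporalEdge(i, j, float(i + j + 1))
                 for i in range(5) for j in range(i + 1, 5)]
        g = TemporalGraph(edges)
        with pytest.raises(ValueError, match="never-connected"):
            temporal_split(g, pivot_fraction=0.5, seed=0)

    def test_seed_determinism(self, sbm_graph):
        s1 = temporal_split(sbm_graph, seed=7)
        s2 = temporal_split(sbm_graph, seed=7)
        assert s1.train_neg == s2.train_neg
        assert s1.test_neg == s2.test_neg


class TestPairFeatureAndLoss:
    def test_concatenation(self):
        out = pair_feature(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert np.array_equal(out, [1, 2, 3, 4])

    def test_zero_vectors(self):
        assert np.array_equal(pair_feature(np.zeros(3), np.zeros(3)),
                              np.zeros(6))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            pair_feature(np.zeros(2), np.zeros(3))

    def test_bce_values(self):
        assert bce_loss(1, 1.0) == pytest.approx(1e-7, abs=1e-8)
        assert bce_loss(1, 0.5) == pytest.approx(np.log(2), abs=1e-12)
        assert bce_loss(0, 0.5) == pytest.approx(np.log(2), abs=1e-12)
        for p_hat in (0.0, 0.1, 0.9, 1.0):
            assert bce_loss(1, p_hat) >= 0
            assert bce_loss(0, p_hat) >= 0


class TestMetrics:
    def test_confusion_hand_case(self):
        m = confusion_report(tp=8, fp=2, fn=2, tn=8)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(0.8)
        assert m["fpr"] == pytest.approx(0.2)

    def test_zero_division_guard(self):
        m = confusion_report(tp=0, fp=0, fn=3, tn=5)
        assert m["precision"] == 0.0 and not m["precision_defined"]

    def test_auroc_equals_rank_statistic(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = np.round(rng.random(200), 2)  # force ties
        assert auroc_score(labels, scores) == pytest.approx(
            mann_whitney_auc(labels, scores), abs=1e-9)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert auroc_score(labels, scores) == pytest.approx(1.0)
        assert aupr_score(labels, scores) == pytest.approx(1.0)

    def test_constant_scores_give_chance(self):
        labels = np.array([0, 1] * 10)
        scores = np.full(20, 0.5)
        assert auroc_score(labels, scores) == pytest.approx(0.5)

    def test_metrics_bounded(self):
        rng = np.random.default_rng(3)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.random(50)
        for v in (auroc_score(labels, scores), aupr_score(labels, scores)):
            assert 0.0 <= v <= 1.0


@pytest.fixture(scope="module")
def trained(sbm_graph, small_series):
    from temporalign import align_series

    aligned, _ = align_series(small_series, "procrustes")
    split = temporal_split(sbm_graph, seed=0)
    model = train(aligned, split, TrainConfig(epochs=40, seed=0))
    return aligned, split, model


class TestTraining:
    def test_loss_decreases(self, trained):
        _, _, model = trained
        assert model.loss_history[-1] < model.loss_history[0]

    def test_seed_determinism(self, trained):
        aligned, split, model = trained
        again = train(aligned, split, TrainConfig(epochs=40, seed=0))
        assert again.loss_history == model.loss_history

    def test_untrained_predictor_is_chance_level(self, small_series):
        rng = np.random.default_rng(1)
        model = LinkPredictor(small_series.width, seed=5)
        n = small_series.X[0].shape[0]
        pairs = [(int(u), int(v)) for u, v in
                 rng.integers(0, n, size=(400, 2)) if u != v]
        labels = rng.integers(0, 2, len(pairs))
        scores = model.scores(small_series, pairs)
        assert auroc_score(labels, scores) == pytest.approx(0.5, abs=0.1)

    def test_evaluate_report(self, trained):
        aligned, split, model = trained
        rep = evaluate(model, split, aligned)
        assert rep.tp + rep.fn == len(split.test_pos)
        assert rep.fp + rep.tn == len(split.test_neg)
        for v in (rep.precision, rep.recall, rep.fpr, rep.auroc, rep.aupr):
            assert 0.0 <= v <= 1.0

    def test_learns_planted_structure(self, trained, sbm_graph):
        _, split, model = trained
        rep = evaluate(model, split, trained[0])
        assert rep.auroc > 0.55  # clear signal on the small fixture
        assert rep.auroc > degree_product_auroc(sbm_graph, split) - 0.25

    def test_divergence_detection(self, trained):
        aligned, split, _ = trained
        bad = [X.copy() for X in aligned.X]
        bad[0][0, 0] = np.nan
        poisoned = StaticEmbeddingSeries(X=bad)
        with pytest.raises(FloatingPointError, match="diverged"):
            train(poisoned, split, TrainConfig(epochs=3, seed=0))
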