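from itertools import combinations

import numpy as np
import pytest

from ddievent.embedding import (
    EmbeddingParams,
    embed_all_sources,
    generate_walks,
    train_embedding,
)
from ddievent.heterograph import build_network
from ddievent.io_model import EventEdgeList, ValidationError
from ddievent.similarity import SimilarityMatrix
from ddievent.io_model import DrugIndex


def single_layer_net(edges, n, seed=0, attr_dim=10):
    el = EventEdgeList(tuple(edges), 1)
    attrs = np.random.default_rng(seed).random((n, attr_dim))
    return build_network(el, attrs)


def two_clique_net(seed):
    edges = []
    for block in (range(10), range(10, 20)):
        edges += [(i, j, 0) for i, j in combinations(block, 2)]
    return single_layer_net(edges, 20, seed=seed)


class TestWalks:
    def test_single_edge_forces_alternation(self):
        net = single_layer_net([(0, 1, 0)], 3)
        params = EmbeddingParams(walk_length=6, walks_per_node=4, seed=0)
        walks = generate_walks(net, 0, params)
        assert walks.shape == (8, 6)  # node 2 is isolated: no walks from it
        for w in walks:
            assert all(w[k] != w[k + 1] and w[k] in (0, 1) for k in range(5))

    def test_isolated_node_contributes_no_walks(self):
        net = single_layer_net([(0, 1, 0)], 5)
        walks = generate_walks(net, 0, EmbeddingParams(seed=0))
        assert not np.isin([2, 3, 4], walks).any()

    def test_invalid_layer_rejected(self):
        net = single_layer_net([(0, 1, 0)], 2)
        with pytest.raises(ValidationError, match="layer"):
            generate_walks(net, 3, EmbeddingParams(seed=0))

    def test_triangle_visits_are_uniform(self):
        # stationary distribution of a walk on a 2-regular graph is uniform
        net = single_layer_net([(0, 1, 0), (1, 2, 0), (0, 2, 0)], 3)
        params = EmbeddingParams(walks_per_node=40, walk_length=100, seed=0)
        walks = generate_walks(net, 0, params)
        freq = np.bincount(walks.ravel(), minlength=3) / walks.size
        np.testing.assert_allclose(freq, 1 / 3, atol=0.02 / 3 + 0.005)

    def test_walks_deterministic_under_seed(self):
        net = two_clique_net(0)
        params = EmbeddingParams(seed=42)
        np.testing.assert_array_equal(
            generate_walks(net, 0, params), generate_walks(net, 0, params)
        )


class TestTrainEmbedding:
    def test_tensor_shape_contract(self):
        el = EventEdgeList(((0, 1, 0), (2, 3, 1), (1, 4, 1)), 2)
        attrs = np.random.default_rng(0).random((5, 7))
        net = build_network(el, attrs)
        t = train_embedding(net, EmbeddingParams(emb_dim=4, epochs=1, seed=0))
        assert t.values.shape == (5, 4, 2)
        assert np.all(np.isfinite(t.values))

    def test_same_seed_identical_tensors(self):
        net = two_clique_net(1)
        params = EmbeddingParams(emb_dim=8, epochs=2, seed=9)
        t1 = train_embedding(net, params)
        t2 = train_embedding(net, params)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_all_layers_empty_rejected(self):
        with pytest.raises(ValidationError):
            el = EventEdgeList(((0, 1, 0),), 1)
            net = build_network(el, np.random.default_rng(0).random((3, 4)))
            empty = build_network(el, net.attributes)
            # remove the only edge to force an empty network
            empty.layers[0].remove_edge(0, 1)
            train_embedding(empty, EmbeddingParams(seed=0))

    def test_two_communities_separate(self):
        net = two_clique_net(3)
        params = EmbeddingParams(
            emb_dim=16, edge_dim=4, walks_per_node=10, walk_length=8,
            window=3, epochs=10, seed=3,
        )
        v = train_embedding(net, params).values[:, :, 0]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        cos = v @ v.T
        same = [(i, j) for i in range(20) for j in range(20)
                if i != j and (i < 10) == (j < 10)]
        cross = [(i, j) for i in range(10) for j in range(10, 20)]
        within = np.mean([cos[i, j] for i, j in same])
        between = np.mean([cos[i, j] for i, j in cross])
        assert within > between + 0.05

    def test_isolated_in_layer_nodes_get_finite_vectors(self):
        # layer 1 touches only drugs 4..5; the rest still need vectors there
        el = EventEdgeList(((0, 1, 0), (2, 3, 0), (4, 5, 1)), 2)
        attrs = np.random.default_rng(0).random((6, 5))
        net = build_network(el, attrs)
        t = train_embedding(net, EmbeddingParams(emb_dim=4, epochs=1, seed=0))
        assert np.all(np.isfinite(t.values[:, :, 1]))


class TestEmbedAllSources:
    def test_one_tensor_per_source(self, tiny_similarities, tiny_dataset, fast_embed_params):
        _, _, edges, _, _ = tiny_dataset
        tensors = embed_all_sources(tiny_similarities, edges, fast_embed_params)
        assert len(tensors) == 2
        assert len({t.values.shape for t in tensors}) == 1
        assert [t.source for t in tensors] == ["structure", "target"]

    def test_identical_attributes_identical_tensors(self, tiny_dataset, fast_embed_params):
        _, _, edges, _, _ = tiny_dataset
        rng = np.random.default_rng(0)
        bits = rng.random((120, 120))
        sym = (bits + bits.T) / 2
        np.fill_diagonal(sym, 1.0)
        drugs = DrugIndex(tuple(f"D{i:04d}" for i in range(120)))
        sims = [SimilarityMatrix("a", drugs, sym), SimilarityMatrix("b", drugs, sym)]
        t1, t2 = embed_all_sources(sims, edges, fast_embed_params)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_no_sources_rejected(self, tiny_dataset, fast_embed_params):
        _, _, edges, _, _ = tiny_dataset
        with pytest.raises(ValidationError):
            embed_all_sources([], edges, fast_embed_params)
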