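import networkx as nx
import numpy as np
import pytest

from m6age.graph_embeddings import (EmbeddingParams, generate_walks,
                                    grarep_embed, modularity_matrix,
                                    node2vec_embed, socdim_embed,
                                    transition_matrix)
from m6age.similarity_graph import SimilarityGraph


def graph_from_nx(g):
    adj = nx.to_numpy_array(g)
    return SimilarityGraph.from_adjacency(adj)


@pytest.fixture
def barbell():
    """Two 4-cliques joined by one edge."""
    g = nx.Graph()
    for base in (0, 4):
        for i in range(4):
            for j in range(i + 1, 4):
                g.add_edge(base + i, base + j)
    g.add_edge(3, 4)
    return graph_from_nx(g)


@pytest.fixture
def two_cliques():
    """Two 5-cliques joined by one edge."""
    g = nx.Graph()
    for base in (0, 5):
        for i in range(5):
            for j in range(i + 1, 5):
                g.add_edge(base + i, base + j)
    g.add_edge(4, 5)
    return graph_from_nx(g)


@pytest.fixture
def random_graph():
    g = nx.connected_watts_strogatz_graph(30, 4, 0.3, seed=1)
    return graph_from_nx(g)


class TestSocDim:
    def test_modularity_rows_sum_to_zero(self, random_graph):
        B = modularity_matrix(random_graph.adjacency)
        np.testing.assert_allclose(B.sum(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(B, B.T)

    def test_barbell_leading_eigenvector_separates_cliques(self, barbell):
        emb = socdim_embed(barbell, EmbeddingParams(dim=1))
        signs = np.sign(emb.matrix[:, 0])
        assert len(set(signs[:4])) == 1
        assert len(set(signs[4:])) == 1
        assert signs[0] != signs[4]

    def test_barbell_matches_dense_eigensolver(self, barbell):
        B = modularity_matrix(barbell.adjacency)
        vals = np.linalg.eigvalsh(B)
        emb = socdim_embed(barbell, EmbeddingParams(dim=1))
        Bv = B @ emb.matrix[:, 0]
        lam = float(emb.matrix[:, 0] @ Bv)
        assert lam == pytest.approx(vals[-1], abs=1e-8)

    def test_eigenpair_residuals(self, random_graph):
        d = 5
        emb = socdim_embed(random_graph, EmbeddingParams(dim=d))
        B = modularity_matrix(random_graph.adjacency)
        for j in range(d):
            v = emb.matrix[:, j]
            lam = v @ (B @ v)
            assert np.linalg.norm(B @ v - lam * v) <= 1e-6

    def test_shape_and_dim_guard(self, random_graph):
        emb = socdim_embed(random_graph, EmbeddingParams(dim=4))
        assert emb.matrix.shape == (30, 4)
        with pytest.raises(ValueError, match="dim"):
            socdim_embed(random_graph, EmbeddingParams(dim=30))

    def test_relabeling_equivariance_up_to_sign(self, random_graph):
        adj = random_graph.adjacency
        rng = np.random.default_rng(2)
        perm = rng.permutation(adj.shape[0])
        permuted = SimilarityGraph.from_adjacency(adj[np.ix_(perm, perm)])
        a = socdim_embed(random_graph, EmbeddingParams(dim=3)).matrix
        b = socdim_embed(permuted, EmbeddingParams(dim=3)).matrix
        # undo the permutation; columns may flip sign only
        b_unperm = np.empty_like(b)
        b_unperm[perm] = b
        for j in range(3):
            assert (np.allclose(a[:, j], b_unperm[:, j], atol=1e-6)
                    or np.allclose(a[:, j], -b_unperm[:, j], atol=1e-6))


class TestNode2Vec:
    def test_walks_follow_edges(self, random_graph):
        params = EmbeddingParams(dim=4, seed=3, walks_per_node=2,
                                 walk_length=10)
        walks = generate_walks(random_graph, params)
        adj = random_graph.adjacency
        for walk in walks:
            for a, b in zip(walk[:-1], walk[1:]):
                assert adj[a, b] == 1

    def test_star_center_next_hop_uniform(self):
        """With p=q=1 the bias disappears; from the star's center every leaf
        is equally likely, within 3 sigma of binomial sampling noise."""
        n_leaves = 8
        g = graph_from_nx(nx.star_graph(n_leaves))  # node 0 is the center
        params = EmbeddingParams(dim=2, seed=4, p=1.0, q=1.0,
                                 walks_per_node=250, walk_length=14)
        walks = generate_walks(g, params)
        counts = np.zeros(n_leaves + 1)
        n_from_center = 0
        for walk in walks:
            for a, b in zip(walk[1:-1], walk[2:]):  # second-order steps only
                if a == 0:
                    counts[b] += 1
                    n_from_center += 1
        assert n_from_center >= 10_000
        p = 1.0 / n_leaves
        sigma = np.sqrt(n_from_center * p * (1 - p))
        np.testing.assert_allclose(counts[1:], n_from_center * p,
                                   atol=3 * sigma)
        assert counts[0] == 0

    def test_fixed_seed_reproduces_walks_and_embedding(self, random_graph):
        params = EmbeddingParams(dim=4, seed=5, walks_per_node=3,
                                 walk_length=8, epochs=1)
        w1 = generate_walks(random_graph, params)
        w2 = generate_walks(random_graph, params)
        np.testing.assert_array_equal(w1, w2)
        e1 = node2vec_embed(random_graph, params).matrix
        e2 = node2vec_embed(random_graph, params).matrix
        np.testing.assert_array_equal(e1, e2)

    def test_walk_length_guard(self, random_graph):
        with pytest.raises(ValueError, match="walk_length"):
            EmbeddingParams(walk_length=1)

    def test_embedding_finite_and_shaped(self, random_graph):
        emb = node2vec_embed(random_graph,
                             EmbeddingParams(dim=6, seed=6,
                                             walks_per_node=5, epochs=1))
        assert emb.matrix.shape == (30, 6)
        assert np.all(np.isfinite(emb.matrix))

    def test_return_bias_prefers_backtracking(self):
        """A tiny return parameter p makes the walk revisit the previous
        node far more often than an unbiased walk would."""
        g = graph_from_nx(nx.cycle_graph(10))
        base = EmbeddingParams(dim=2, seed=7, walks_per_node=50,
                               walk_length=20)
        biased = EmbeddingParams(dim=2, seed=7, walks_per_node=50,
                                 walk_length=20, p=0.01)

        def backtrack_rate(params):
            walks = generate_walks(g, params)
            back = total = 0
            for walk in walks:
                for i in range(2, len(walk)):
                    total += 1
                    back += walk[i] == walk[i - 2]
            return back / total

        assert backtrack_rate(biased) > backtrack_rate(base) + 0.2


class TestGraRep:
    def test_transition_rows_sum_to_one(self, random_graph):
        T = transition_matrix(random_graph.adjacency)
        np.testing.assert_allclose(T.sum(axis=1), 1.0)

    def test_concatenated_width(self, random_graph):
        emb = grarep_embed(random_graph,
                           EmbeddingParams(dim=4, k_max=4, seed=8))
        assert emb.matrix.shape == (30, 16)

    def test_two_clique_cosine_separation(self, two_cliques):
        emb = grarep_embed(two_cliques,
                           EmbeddingParams(dim=3, k_max=2, seed=9)).matrix
        norm = emb / np.linalg.norm(emb, axis=1, keepdims=True)
        cos = norm @ norm.T
        within = np.concatenate([cos[:5, :5][np.triu_indices(5, 1)],
                                 cos[5:, 5:][np.triu_indices(5, 1)]])
        between = cos[:5, 5:].ravel()
        assert within.mean() > between.mean()

    def test_deterministic(self, random_graph):
        p = EmbeddingParams(dim=4, k_max=2, seed=10)
        a = grarep_embed(random_graph, p).matrix
        b = grarep_embed(random_graph, p).matrix
        np.testing.assert_array_equal(a, b)


class TestCommonContracts:
    def test_row_order_follows_node_ids(self, random_graph):
        for emb in (socdim_embed(random_graph, EmbeddingParams(dim=3)),
                    grarep_embed(random_graph,
                                 EmbeddingParams(dim=3, k_max=2))):
            assert emb.sample_ids == random_graph.node_ids

    def test_unbuilt_graph_rejected(self):
        g = SimilarityGraph(W=np.zeros((3, 3)), C=np.zeros((3, 3)),
                            node_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match="not built"):
            socdim_embed(g, EmbeddingParams(dim=1))
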