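import networkx as nx
import numpy as np
import pytest

from string2go import (MashupEmbedding, Node2VecEmbedding, WeightedNetwork,
                       mashup_embed, node2vec_walks, rwr_diffusion,
                       skipgram_embed)
from string2go.embedding import node2vec_transition_probs

from conftest import make_network


def random_net(rng, n=20, p=0.3):
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
    # guarantee no isolated node so power iteration and direct solve agree
    nodes = list(g.nodes)
    for i in range(n):
        g.add_edge(nodes[i], nodes[(i + 1) % n])
    wg = nx.Graph()
    for u, v in g.edges:
        wg.add_edge(f"n{u}", f"n{v}", weight=float(rng.uniform(0.1, 1.0)))
    return WeightedNetwork(graph=wg)


class TestRWR:
    def test_single_isolated_node(self):
        g = nx.Graph()
        g.add_node("a")
        diff = rwr_diffusion(WeightedNetwork(graph=g))
        assert diff.states.tolist() == [[1.0]]

    def test_two_node_closed_form(self):
        net = make_network([("a", "b", 1.0)])
        diff = rwr_diffusion(net, restart_prob=0.5)
        np.testing.assert_allclose(diff.states[0], [2 / 3, 1 / 3],
                                   atol=1e-10)
        np.testing.assert_allclose(diff.states[1], [1 / 3, 2 / 3],
                                   atol=1e-10)

    def test_power_iteration_matches_direct_solve(self, rng):
        for _ in range(5):
            net = random_net(rng)
            direct = rwr_diffusion(net).states
            power = rwr_diffusion(net, direct_solve_max_nodes=0).states
            np.testing.assert_allclose(power, direct, atol=1e-6)

    def test_rows_are_probability_vectors(self, rng):
        net = random_net(rng)
        diff = rwr_diffusion(net, restart_prob=0.3)
        np.testing.assert_allclose(diff.states.sum(axis=1), 1.0, atol=1e-8)
        assert (diff.states >= 0).all()
        assert (np.diag(diff.states) >= 0.3 - 1e-12).all()

    def test_permutation_equivariance(self, rng):
        net = random_net(rng, n=8)
        diff = rwr_diffusion(net)
        perm = list(rng.permutation(net.nodes))
        g2 = nx.Graph()
        g2.add_nodes_from(perm)
        for u, v, w in net.edges():
            g2.add_edge(u, v, weight=w)
        diff2 = rwr_diffusion(WeightedNetwork(graph=g2))
        idx = [net.nodes.index(p) for p in perm]
        np.testing.assert_allclose(diff2.states,
                                   diff.states[np.ix_(idx, idx)], atol=1e-12)

    def test_negative_weight_rejected(self):
        net = make_network([("a", "b", -0.5)])
        with pytest.raises(ValueError, match="negative"):
            rwr_diffusion(net)

    def test_invalid_restart_prob(self):
        net = make_network([("a", "b", 1.0)])
        with pytest.raises(ValueError):
            rwr_diffusion(net, restart_prob=1.5)


class TestMashup:
    def test_full_rank_reconstruction(self, rng):
        net = random_net(rng, n=10)
        diff = rwr_diffusion(net)
        emb = mashup_embed(diff, d=10)
        sigma = emb.params["singular_values"]
        U = emb.vectors / np.sqrt(sigma)
        recon = U * sigma @ emb.params["vt"]
        np.testing.assert_allclose(recon, diff.states, atol=1e-6)

    def test_identical_diffusion_rows_embed_identically(self):
        from string2go.embedding import DiffusionMatrix
        S = np.array([[0.5, 0.25, 0.25],
                      [0.5, 0.25, 0.25],
                      [0.2, 0.4, 0.4]])
        diff = DiffusionMatrix(nodes=["a", "b", "c"], states=S,
                               restart_prob=0.5)
        emb = mashup_embed(diff, d=2)
        np.testing.assert_allclose(emb.vectors[0], emb.vectors[1], atol=1e-12)

    def test_reconstruction_error_non_increasing_in_d(self, rng):
        net = random_net(rng, n=10)
        diff = rwr_diffusion(net)
        errors = []
        for d in (2, 4):
            emb = mashup_embed(diff, d=d)
            Q, _ = np.linalg.qr(emb.vectors)
            proj = Q @ (Q.T @ diff.states)
            errors.append(np.linalg.norm(diff.states - proj))
        assert errors[1] <= errors[0] + 1e-12

    def test_d_clamped_to_node_count(self, rng):
        diff = rwr_diffusion(random_net(rng, n=5))
        assert mashup_embed(diff, d=100).d == diff.states.shape[0]

    def test_invalid_d(self, rng):
        diff = rwr_diffusion(random_net(rng, n=5))
        with pytest.raises(ValueError):
            mashup_embed(diff, d=0)


class TestNode2VecWalks:
    def test_second_order_bias_enumeration(self, triangle_pendant):
        opts, probs = node2vec_transition_probs(
            triangle_pendant, prev="b", current="c", p=1.0, q=2.0)
        got = dict(zip(opts, probs))
        assert got["a"] == pytest.approx(0.4)
        assert got["b"] == pytest.approx(0.4)
        assert got["d"] == pytest.approx(0.2)

    def test_return_parameter_bias(self, triangle_pendant):
        opts, probs = node2vec_transition_probs(
            triangle_pendant, prev="b", current="c", p=0.25, q=2.0)
        got = dict(zip(opts, probs))
        assert got["b"] > got["a"]  # 1/p = 4 outweighs the distance-1 factor

    def test_q1_p1_matches_first_order_weighted_walk(self):
        # degenerate parameters: second-order bias vanishes
        net = make_network([("a", "b", 0.2), ("a", "c", 0.8)])
        n_steps = 20000
        counts = {"b": 0, "c": 0}
        walks = node2vec_walks(net, walk_length=2,
                               walks_per_node=n_steps // 3, p=1.0, q=1.0,
                               seed=7)
        for w in walks.walks:
            if w[0] == "a" and len(w) > 1:
                counts[w[1]] += 1
        total = counts["b"] + counts["c"]
        freq_b = counts["b"] / total
        sigma = np.sqrt(0.2 * 0.8 / total)
        assert abs(freq_b - 0.2) < 3 * sigma

    def test_isolated_node_single_walk(self):
        g = nx.Graph()
        g.add_node("solo")
        g.add_edge("a", "b", weight=1.0)
        walks = node2vec_walks(WeightedNetwork(graph=g), seed=0)
        assert [["solo"]] == [w for w in walks.walks if w[0] == "solo"][:1]

    def test_walks_respect_adjacency_and_length(self, triangle_pendant):
        corpus = node2vec_walks(triangle_pendant, walk_length=10,
                                walks_per_node=3, seed=0)
        g = triangle_pendant.graph
        for walk in corpus.walks:
            assert len(walk) <= 10
            for a, b in zip(walk, walk[1:]):
                assert g.has_edge(a, b)

    def test_invalid_pq(self, triangle_pendant):
        with pytest.raises(ValueError):
            node2vec_walks(triangle_pendant, p=0.0)

    def test_seeded_reproducibility(self, triangle_pendant):
        w1 = node2vec_walks(triangle_pendant, seed=3).walks
        w2 = node2vec_walks(triangle_pendant, seed=3).walks
        assert w1 == w2


class TestSkipgram:
    @pytest.fixture(scope="class")
    def clique_corpus(self):
        g = nx.Graph()
        for base in ("x", "y"):
            for i in range(10):
                for j in range(i + 1, 10):
                    g.add_edge(f"{base}{i}", f"{base}{j}", weight=1.0)
        net = WeightedNetwork(graph=g)
        return net, node2vec_walks(net, seed=1)

    def test_community_separation(self, clique_corpus):
        _, corpus = clique_corpus
        emb = skipgram_embed(corpus, d=16, seed=1)
        V = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        idx = {p: i for i, p in enumerate(emb.proteins)}
        within = np.mean([V[idx[f"x{i}"]] @ V[idx[f"x{j}"]]
                          for i in range(10) for j in range(i + 1, 10)])
        between = np.mean([V[idx[f"x{i}"]] @ V[idx[f"y{j}"]]
                           for i in range(10) for j in range(10)])
        assert within > between

    def test_output_shape(self, clique_corpus):
        _, corpus = clique_corpus
        emb = skipgram_embed(corpus, d=8, seed=0, epochs=1)
        assert emb.vectors.shape == (len(corpus.node_set()), 8)

    def test_absent_node_gets_zero_vector(self, clique_corpus):
        net, corpus = clique_corpus
        emb = skipgram_embed(corpus, d=8, seed=0, epochs=1,
                             all_nodes=net.nodes + ["ghost"])
        assert np.all(emb.vectors[emb.proteins.index("ghost")] == 0)

    def test_invalid_d(self, clique_corpus):
        _, corpus = clique_corpus
        with pytest.raises(ValueError):
            skipgram_embed(corpus, d=0)


class TestEstimators:
    def test_planted_partition_linear_separability(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        from string2go import SyntheticSpec, simulate_network

        spec = SyntheticSpec(n_proteins=200, k_communities=2, seed=0)
        net, assign = simulate_network(spec)
        for est in (Node2VecEmbedding(d=32, seed=0), MashupEmbedding(d=32)):
            emb = est.fit_transform(net)
            y = np.array([assign[p] for p in emb.proteins])
            acc = cross_val_score(LogisticRegression(max_iter=5000),
                                  emb.vectors, y, cv=5).mean()
            assert acc > 0.9, est

    def test_tsv_round_trip(self, tmp_path, rng):
        net = random_net(rng, n=6)
        emb = MashupEmbedding(d=4).fit_transform(net)
        path = tmp_path / "emb.tsv"
        emb.to_tsv(path)
        from string2go import EmbeddingMatrix
        emb2 = EmbeddingMatrix.from_tsv(path)
        assert emb2.proteins == emb.proteins
        np.testing.assert_allclose(emb2.vectors, emb.vectors, rtol=1e-6)
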