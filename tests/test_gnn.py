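"""GIN encoder, link scoring, negative sampling and pretraining."""

import numpy as np
import pytest

from drivernet.gnn import (
    EmbeddingTable,
    GnnConfig,
    LinkExample,
    encode,
    gin_block,
    gin_conv,
    init_parameters,
    link_loss,
    pretrain,
    sample_negatives,
    score_link,
    score_link_relational,
)
from drivernet.graph_io import KnowledgeGraph, RelationLabel


def _line_graph(*pairs, relation="binds"):
    r = RelationLabel(relation, "toy")
    return KnowledgeGraph.build([(u, r, v) for u, v in pairs])


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(dim=0), dict(dim=-4), dict(epochs=0), dict(n_layers=0),
         dict(learning_rate=0.0), dict(negatives_per_positive=0)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GnnConfig(**kwargs)


class TestInitParameters:
    def test_same_seed_bit_identical(self, toy_graph):
        cfg = GnnConfig(dim=16, seed=1)
        p1 = init_parameters(toy_graph, cfg)
        p2 = init_parameters(toy_graph, cfg)
        for a, b in zip(p1.flat_arrays(), p2.flat_arrays()):
            assert np.array_equal(a, b)

    def test_different_seeds_differ(self, toy_graph):
        p1 = init_parameters(toy_graph, GnnConfig(dim=16, seed=1))
        p2 = init_parameters(toy_graph, GnnConfig(dim=16, seed=2))
        assert not np.array_equal(p1.node_embedding, p2.node_embedding)

    def test_embedding_shape(self):
        g = _line_graph(("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"))
        p = init_parameters(g, GnnConfig(dim=16, seed=0))
        assert p.node_embedding.shape == (5, 16)


class TestGinConv:
    def test_isolated_node_identity(self):
        g = KnowledgeGraph.build([], extra_nodes=["X"])
        z = EmbeddingTable(["X"], np.array([[1.0, 2.0]]))
        out = gin_conv(z, g, update_map=None, epsilon=0.0)
        assert np.allclose(out["X"], [1.0, 2.0])

    def test_single_edge_neighbor_sum(self):
        g = _line_graph(("A", "B"))
        z = EmbeddingTable(["A", "B"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        out = gin_conv(z, g, update_map=None, epsilon=0.0)
        assert np.allclose(out["A"], [1.0, 1.0])
        assert np.allclose(out["B"], [1.0, 1.0])

    def test_epsilon_scales_self_term(self):
        g = _line_graph(("A", "B"))
        z = EmbeddingTable(["A", "B"], np.array([[1.0], [10.0]]))
        out = gin_conv(z, g, epsilon=0.5)
        assert np.allclose(out["A"], [1.5 * 1.0 + 10.0])

    def test_permutation_equivariance(self, rng):
        """Relabeling nodes then convolving equals convolving then relabeling."""
        nodes = [f"n{i}" for i in range(8)]
        r = RelationLabel("binds", "toy")
        edges = []
        for i in range(8):
            for j in range(i + 1, 8):
                if rng.random() < 0.4:
                    edges.append((nodes[i], r, nodes[j]))
        g = KnowledgeGraph.build(edges, extra_nodes=nodes)
        z = rng.standard_normal((8, 3))
        table = EmbeddingTable(g.nodes, z)
        out = gin_conv(table, g, update_map=lambda m: np.tanh(m))
        for _ in range(5):
            perm = {n: f"m{k}" for n, k in zip(nodes, rng.permutation(8))}
            g_p = KnowledgeGraph.build(
                [(perm[u], rr, perm[v]) for u, rr, v in g.edges],
                extra_nodes=[perm[n] for n in nodes],
            )
            table_p = EmbeddingTable(
                g_p.nodes, np.array([table[inv] for inv in
                                     [next(k for k, w in perm.items() if w == n)
                                      for n in g_p.nodes]])
            )
            out_p = gin_conv(table_p, g_p, update_map=lambda m: np.tanh(m))
            for n in nodes:
                assert np.allclose(out[n], out_p[perm[n]])


class TestGinBlock:
    def test_zero_weights_collapse(self, toy_graph):
        """With W_(r)=0 every node's output is relu(sum_r b_(r)), z-independent."""
        from drivernet.gnn import LayerParams

        c = 3
        rng = np.random.default_rng(0)
        layer = LayerParams(
            mlp_w1=np.eye(c), mlp_b1=np.zeros(c),
            mlp_w2=np.eye(c), mlp_b2=np.zeros(c),
            rel_w={r: np.zeros((c, c)) for r in toy_graph.relations},
            rel_b={r: np.array([1.0, -2.0, 0.5]) for r in toy_graph.relations},
        )
        z = EmbeddingTable(toy_graph.nodes, rng.standard_normal((4, c)))
        out = gin_block(z, toy_graph, layer)
        expected = np.maximum(2 * np.array([1.0, -2.0, 0.5]), 0.0)
        for n in toy_graph.nodes:
            assert np.allclose(out[n], expected)

    def test_single_relation_reduction(self):
        """|R|=1 block equals relu(W·relu(GINConv MLP) + b) computed by hand."""
        from drivernet.gnn import LayerParams

        g = _line_graph(("A", "B"))
        rng = np.random.default_rng(1)
        c = 2
        r = g.relations[0]
        layer = LayerParams(
            mlp_w1=rng.standard_normal((c, c)), mlp_b1=rng.standard_normal(c),
            mlp_w2=rng.standard_normal((c, c)), mlp_b2=rng.standard_normal(c),
            rel_w={r: rng.standard_normal((c, c))}, rel_b={r: rng.standard_normal(c)},
        )
        z = rng.standard_normal((2, c))
        out = gin_block(EmbeddingTable(g.nodes, z), g, layer)
        agg = z + z[::-1]  # each node's only neighbor is the other
        h = np.maximum(np.maximum(agg @ layer.mlp_w1 + layer.mlp_b1, 0)
                       @ layer.mlp_w2 + layer.mlp_b2, 0)
        expected = np.maximum(h @ layer.rel_w[r] + layer.rel_b[r], 0)
        assert np.allclose(out.matrix, expected)

    def test_two_relation_hand_arithmetic(self):
        """Two-relation toy with hand-set 2x2 weights vs a scripted loop oracle."""
        from drivernet.gnn import LayerParams

        r1 = RelationLabel("a", "toy")
        r2 = RelationLabel("b", "toy")
        g = KnowledgeGraph.build([("X", r1, "Y"), ("Y", r2, "Z")])
        c = 2
        layer = LayerParams(
            mlp_w1=np.eye(c), mlp_b1=np.zeros(c),
            mlp_w2=np.eye(c), mlp_b2=np.zeros(c),
            rel_w={r1: np.array([[1.0, 0.0], [0.0, 2.0]]),
                   r2: np.array([[0.0, 1.0], [1.0, 0.0]])},
            rel_b={r1: np.array([0.1, 0.1]), r2: np.array([-0.1, -0.1])},
        )
        z = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])  # X, Y, Z sorted
        out = gin_block(EmbeddingTable(g.nodes, z), g, layer)
        # independent oracle with explicit per-node loops
        idx = {n: i for i, n in enumerate(g.nodes)}
        neigh = {r1: {"X": ["Y"], "Y": ["X"], "Z": []},
                 r2: {"X": [], "Y": ["Z"], "Z": ["Y"]}}
        for n in g.nodes:
            acc = np.zeros(c)
            for r in (r1, r2):
                agg = z[idx[n]] + sum((z[idx[m]] for m in neigh[r][n]), np.zeros(c))
                h = np.maximum(agg, 0)  # identity MLP + inner relu
                acc = acc + h @ layer.rel_w[r] + layer.rel_b[r]
            assert np.allclose(out[n], np.maximum(acc, 0))


class TestEncode:
    def test_output_dim_is_c_for_any_depth(self, toy_graph):
        for n_layers in (1, 2, 3):
            cfg = GnnConfig(dim=8, n_layers=n_layers, seed=0)
            table = encode(toy_graph, init_parameters(toy_graph, cfg), cfg)
            assert table.dim == 8 and len(table) == toy_graph.n_nodes

    def test_degenerate_projection_recovers_last_block(self, toy_graph):
        cfg = GnnConfig(dim=4, n_layers=1, seed=3)
        params = init_parameters(toy_graph, cfg)
        # projection = zero on z^0 slot, identity on the block-output slot
        params.projection[:] = 0.0
        params.projection[4:, :] = np.eye(4)
        params.projection_b[:] = 0.0
        table = encode(toy_graph, params, cfg)
        block = gin_block(
            EmbeddingTable(toy_graph.nodes, params.node_embedding),
            toy_graph, params.layers[0],
        )
        assert np.allclose(table.matrix, block.matrix)

    def test_isomorphic_components_match(self):
        """Mirrored components with identical initial vectors embed identically."""
        r = RelationLabel("binds", "toy")
        g = KnowledgeGraph.build(
            [("A1", r, "B1"), ("B1", r, "C1"), ("A2", r, "B2"), ("B2", r, "C2")]
        )
        cfg = GnnConfig(dim=4, n_layers=2, seed=5)
        params = init_parameters(g, cfg)
        idx = {n: i for i, n in enumerate(g.nodes)}
        for a, b in (("A1", "A2"), ("B1", "B2"), ("C1", "C2")):
            params.node_embedding[idx[b]] = params.node_embedding[idx[a]]
        table = encode(g, params, cfg)
        for a, b in (("A1", "A2"), ("B1", "B2"), ("C1", "C2")):
            assert np.allclose(table[a], table[b])


class TestScoring:
    def test_zero_vectors_half(self):
        assert score_link(np.zeros(4), np.zeros(4)) == 0.5

    def test_unit_dot(self):
        e1 = np.array([1.0, 0.0])
        assert score_link(e1, e1) == pytest.approx(0.7310585786, abs=1e-9)

    def test_score_symmetry_sums_to_one(self, rng):
        for _ in range(20):
            u, v = rng.standard_normal((2, 6))
            assert score_link(u, v) + score_link(u, -v) == pytest.approx(1.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            score_link(np.zeros(3), np.zeros(4))

    def test_relational_identity_diag_equals_plain(self, rng):
        u, v = rng.standard_normal((2, 5))
        assert score_link_relational(u, v, np.ones(5)) == pytest.approx(score_link(u, v))

    def test_relational_zero_diag(self, rng):
        u, v = rng.standard_normal((2, 5))
        assert score_link_relational(u, v, np.zeros(5)) == 0.5

    def test_relational_hand_arithmetic(self):
        # (1,2)·diag(2,1)·(3,-1) = 6 - 2 = 4 → sigma(4)
        p = score_link_relational(
            np.array([1.0, 2.0]), np.array([3.0, -1.0]), np.array([2.0, 1.0])
        )
        assert p == pytest.approx(0.9820137900, abs=1e-6)


class TestSampleNegatives:
    def test_degenerate_single_node(self):
        r = RelationLabel("binds", "toy")
        g = KnowledgeGraph.build([("A", r, "A")])
        pos = [LinkExample("A", r, "A", "positive")]
        neg = sample_negatives(pos, g, np.random.default_rng(0))
        assert neg[0].v == "A" and neg[0].polarity == "negative"

    def test_seed_reproducible(self, toy_graph):
        pos = [LinkExample(u, r, v, "positive") for u, r, v in toy_graph.edges]
        n1 = sample_negatives(pos, toy_graph, np.random.default_rng(3), 2)
        n2 = sample_negatives(pos, toy_graph, np.random.default_rng(3), 2)
        assert n1 == n2
        assert len(n1) == 2 * len(pos)

    def test_uniform_over_nodes(self):
        r = RelationLabel("binds", "toy")
        nodes = [f"n{i}" for i in range(10)]
        g = KnowledgeGraph.build([(nodes[0], r, nodes[1])], extra_nodes=nodes)
        pos = [LinkExample(nodes[0], r, nodes[1], "positive")] * 10_000
        neg = sample_negatives(pos, g, np.random.default_rng(11))
        counts = {n: 0 for n in nodes}
        for ex in neg:
            counts[ex.v] += 1
        sigma = np.sqrt(10_000 * 0.1 * 0.9)
        for n in nodes:
            assert abs(counts[n] - 1000) < 3 * sigma

    def test_empty_batch_rejected(self, toy_graph):
        with pytest.raises(ValueError):
            sample_negatives([], toy_graph, np.random.default_rng(0))


class TestLinkLoss:
    def test_zero_logits_two_ln_two(self):
        assert link_loss([0.0], [0.0]) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_confident_limit_vanishes(self):
        assert link_loss([30.0], [-30.0]) == pytest.approx(0.0, abs=1e-10)

    def test_closed_form_fixture(self):
        # softplus(-1) + softplus(-1) = 2 ln(1 + e^-1)
        assert link_loss([1.0], [-1.0]) == pytest.approx(
            2 * np.log(1 + np.exp(-1)), abs=1e-12
        )

    def test_nonnegative_property(self, rng):
        for _ in range(50):
            pos, neg = rng.standard_normal((2, 8)) * 5
            assert link_loss(pos, neg) >= 0.0

    def test_nan_rejected(self):
        with pytest.raises(FloatingPointError):
            link_loss([np.nan], [0.0])

    def test_count_mismatch(self):
        with pytest.raises(ValueError):
            link_loss([0.0, 1.0], [0.0])


class TestPretrain:
    def test_loss_decreases_at_reference_settings(self, block_graph):
        """Epoch-50 mean loss < epoch-1 mean loss at lr 1e-4, 50 epochs."""
        cfg = GnnConfig(dim=16, epochs=50, learning_rate=1e-4, seed=7)
        _, _, trace = pretrain(block_graph, cfg)
        assert len(trace) == 50
        assert trace[-1] < trace[0]

    def test_seed_determinism_end_to_end(self, block_graph):
        cfg = GnnConfig(dim=16, epochs=5, learning_rate=0.01, seed=7)
        _, t1, l1 = pretrain(block_graph, cfg)
        _, t2, l2 = pretrain(block_graph, cfg)
        assert np.array_equal(t1.matrix, t2.matrix)
        assert np.array_equal(l1, l2)

    def test_heldout_edges_score_above_nonedges(self, block_graph):
        """Link-prediction skill on a 2-block graph with 10% edges held out."""
        from drivernet.graph_io import KnowledgeGraph

        rng = np.random.default_rng(7)
        edges = list(block_graph.edges)
        perm = rng.permutation(len(edges))
        n_held = len(edges) // 10
        held = [edges[i] for i in perm[:n_held]]
        train = [edges[i] for i in perm[n_held:]]
        g_train = KnowledgeGraph.build(train, extra_nodes=block_graph.nodes)
        cfg = GnnConfig(dim=16, epochs=50, learning_rate=0.01, seed=7)
        _, table, _ = pretrain(g_train, cfg)

        edge_pairs = {(u, v) for u, _, v in edges} | {(v, u) for u, _, v in edges}
        neg_pairs = []
        while len(neg_pairs) < n_held:
            u, v = rng.choice(block_graph.nodes, size=2, replace=False)
            if (u, v) not in edge_pairs:
                neg_pairs.append((u, v))
        pos = np.mean([score_link(table[u], table[v]) for u, _, v in held])
        neg = np.mean([score_link(table[u], table[v]) for u, v in neg_pairs])
        assert pos > neg

    def test_edgeless_graph_rejected(self):
        g = KnowledgeGraph.build([], extra_nodes=["A", "B"])
        with pytest.raises(ValueError):
            pretrain(g, GnnConfig(dim=4, epochs=1))


class TestEmbeddingTableIO:
    def test_tsv_round_trip(self, pretrained):
        import io

        _, _, table, _ = pretrained
        buf = io.StringIO()
        table.to_tsv(buf)
        buf.seek(0)
        table2 = EmbeddingTable.from_tsv(buf)
        assert table2.nodes == table.nodes
        assert np.array_equal(table2.matrix, table.matrix)
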