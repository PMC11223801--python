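"""HGT encoder: attention normalization, message/aggregate semantics, and
equivalence with an independent dense per-node oracle."""

import numpy as np
import pytest

import hgtlink as hl
from hgtlink.autodiff import Tensor
from hgtlink.encoder import EncoderConfig, HGTEncoder, HGTLayer, UnseenRelationError, _tk
from hgtlink.graph import ConfigurationError
from oracles import dense_layer_forward, random_heterograph


def make_layer(counts, edges, d_model=8, heads=2, seed=0, activation="gelu"):
    rng = np.random.Generator(np.random.PCG64(seed))
    return HGTLayer(list(counts), list(edges), d_model, heads, rng, activation)


def random_states(counts, d_model, rng):
    return {t: rng.standard_normal((n, d_model)) for t, n in counts.items()}


def set_identity_params(layer, mu=1.0):
    """Identity projections / bilinear maps and zero biases for hand checks."""
    d, h, dh = layer.d_model, layer.num_heads, layer.d_head
    for linmap in (layer.k_lin, layer.q_lin, layer.m_lin, layer.a_lin):
        for lin in linmap.values():
            lin.weight.data = np.eye(d)
            lin.bias.data = np.zeros(d)
    for key in layer.w_att:
        layer.w_att[key].data = np.stack([np.eye(dh)] * h)
        layer.w_msg[key].data = np.stack([np.eye(dh)] * h)
        layer.mu[key].data = np.array([mu])


class TestAttention:
    def test_single_neighbor_weight_is_exactly_one(self):
        counts = {"a": 2, "b": 1}
        edges = {("a", "r", "b"): np.array([[0, 0]])}
        layer = make_layer(counts, edges)
        h = random_states(counts, 8, np.random.Generator(np.random.PCG64(1)))
        att = layer.attention_coefficients(h, edges)
        np.testing.assert_array_equal(att[("a", "r", "b")], np.ones((1, 2)))

    def test_weights_sum_to_one_per_target_and_head(self, rng):
        for trial in range(25):
            counts, edges = random_heterograph(rng, max_nodes=12, n_types=3, n_relations=4)
            layer = make_layer(counts, edges, seed=trial)
            h = random_states(counts, 8, rng)
            att = layer.attention_coefficients(h, edges)
            sums = {}
            for triple, w in att.items():
                for (_, t_idx), w_e in zip(edges[triple], w):
                    key = (triple[2], int(t_idx))
                    sums[key] = sums.get(key, 0.0) + w_e
            for total in sums.values():
                np.testing.assert_allclose(total, np.ones(2), atol=1e-6)

    def test_hand_computed_two_neighbor_softmax(self):
        # one head, d_head=2: states [[1,0],[0,1]], query [1,0], identity maps,
        # mu=1 -> raw scores [1/sqrt(2), 0], weights softmax of that
        counts = {"s": 2, "t": 1}
        edges = {("s", "r", "t"): np.array([[0, 0], [1, 0]])}
        layer = make_layer(counts, edges, d_model=2, heads=1)
        set_identity_params(layer)
        h = {"s": np.array([[1.0, 0.0], [0.0, 1.0]]), "t": np.array([[1.0, 0.0]])}
        att = layer.attention_coefficients(h, edges)[("s", "r", "t")]
        expected = np.exp([1 / np.sqrt(2), 0.0])
        expected /= expected.sum()
        np.testing.assert_allclose(att[:, 0], expected, atol=1e-12)
        assert att[0, 0] == pytest.approx(0.6697615, abs=1e-6)


class TestMessages:
    def test_identity_maps_give_source_state(self):
        counts = {"s": 3, "t": 2}
        edges = {("s", "r", "t"): np.array([[0, 0], [2, 1]])}
        layer = make_layer(counts, edges, d_model=4, heads=2)
        set_identity_params(layer)
        h = random_states(counts, 4, np.random.Generator(np.random.PCG64(2)))
        msgs = layer.messages(h, edges)[("s", "r", "t")]
        np.testing.assert_allclose(msgs.reshape(2, 4), h["s"][[0, 2]], atol=1e-12)

    def test_zero_source_gives_zero_message(self):
        counts = {"s": 1, "t": 1}
        edges = {("s", "r", "t"): np.array([[0, 0]])}
        layer = make_layer(counts, edges, d_model=4, heads=2)
        for lin in layer.m_lin.values():
            lin.bias.data = np.zeros(4)
        h = {"s": np.zeros((1, 4)), "t": np.ones((1, 4))}
        msgs = layer.messages(h, edges)[("s", "r", "t")]
        np.testing.assert_allclose(msgs, 0.0, atol=1e-12)

    def test_against_dense_matrix_product(self, rng):
        counts = {"s": 3, "t": 2}
        edges = {("s", "r", "t"): np.array([[0, 0], [1, 1], [2, 0]])}
        layer = make_layer(counts, edges, d_model=6, heads=3, seed=4)
        h = random_states(counts, 6, rng)
        msgs = layer.messages(h, edges)[("s", "r", "t")]
        W, b = layer.m_lin["s"].weight.data, layer.m_lin["s"].bias.data
        wm = layer.w_msg[_tk(("s", "r", "t"))].data
        for e, (s_idx, _) in enumerate(edges[("s", "r", "t")]):
            proj = (h["s"][s_idx] @ W + b).reshape(3, 2)
            for i in range(3):
                np.testing.assert_allclose(msgs[e, i], proj[i] @ wm[i], atol=1e-9)


class TestAggregate:
    def test_isolated_node_is_pure_residual(self):
        # no in-edges, zero-bias output projection, activation(0)=0
        counts = {"a": 2}
        edges = {("a", "r", "a"): np.array([[0, 1]])}
        layer = make_layer(counts, edges, d_model=4, heads=2)
        layer.a_lin["a"].bias.data = np.zeros(4)
        h = {"a": Tensor(np.random.default_rng(0).standard_normal((2, 4)))}
        out = layer(h, edges)
        # node 0 has no in-neighbors: output equals previous state exactly
        np.testing.assert_allclose(out["a"].data[0], h["a"].data[0], atol=1e-12)

    def test_single_source_is_convex_endpoint(self):
        counts = {"s": 1, "t": 1}
        edges = {("s", "r", "t"): np.array([[0, 0]])}
        layer = make_layer(counts, edges, d_model=4, heads=2)
        set_identity_params(layer)
        h = {"s": Tensor(np.array([[1.0, 2.0, 3.0, 4.0]])), "t": Tensor(np.zeros((1, 4)))}
        _, att, msgs, dsts = layer._edge_pass(h, edges)
        agg_input = (msgs[("s", "r", "t")].data
                     * att[("s", "r", "t")].data[:, :, None]).reshape(1, 4)
        np.testing.assert_allclose(agg_input, [[1.0, 2.0, 3.0, 4.0]], atol=1e-12)


class TestLayerVsDenseOracle:
    @pytest.mark.parametrize("trial", range(20))
    def test_twenty_random_toy_graphs(self, trial):
        rng = np.random.Generator(np.random.PCG64(100 + trial))
        counts, edges = random_heterograph(rng, max_nodes=10, n_types=3, n_relations=4)
        layer = make_layer(counts, edges, d_model=8, heads=2, seed=trial)
        h_np = random_states(counts, 8, rng)
        ours = layer({t: Tensor(x) for t, x in h_np.items()}, edges)
        oracle = dense_layer_forward(layer, h_np, edges)
        for t in counts:
            np.testing.assert_allclose(ours[t].data, oracle[t], atol=1e-6)

    def test_homogeneous_reduction(self, rng):
        # one node type, identical parameters for every relation: the layer
        # must act as a homogeneous transformer layer on the merged edge set
        counts = {"x": 6}
        edges = {("x", "r1", "x"): np.array([[0, 1], [2, 1], [3, 4]]),
                 ("x", "r2", "x"): np.array([[5, 1], [1, 0]])}
        layer = make_layer(counts, edges, d_model=8, heads=2, seed=1)
        k1, k2 = _tk(("x", "r1", "x")), _tk(("x", "r2", "x"))
        for bank in (layer.w_att, layer.w_msg, layer.mu):
            bank[k2].data = bank[k1].data.copy()
        h = random_states(counts, 8, rng)
        out_split = layer({t: Tensor(x) for t, x in h.items()}, edges)
        merged = {("x", "r1", "x"): np.vstack([edges[("x", "r1", "x")],
                                               edges[("x", "r2", "x")]])}
        out_merged = layer({t: Tensor(x) for t, x in h.items()}, merged)
        np.testing.assert_allclose(out_split["x"].data, out_merged["x"].data, atol=1e-9)


class TestEncoder:
    def build(self, res, cfg=None, seed=0):
        cfg = cfg or EncoderConfig(num_layers=2, d_model=16, num_heads=4)
        rng = np.random.Generator(np.random.PCG64(seed))
        return HGTEncoder.for_graph(res.graph, cfg, rng), cfg

    def test_output_width_is_d_model_for_every_type(self, tiny_graph):
        enc, cfg = self.build(tiny_graph)
        feat = enc.encode(tiny_graph.graph)
        for t, f in feat.items():
            assert f.shape == (tiny_graph.graph.num_nodes(t), cfg.d_model)

    def test_eval_mode_deterministic(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        a = enc.encode(tiny_graph.graph)
        b = enc.encode(tiny_graph.graph)
        for t in a:
            np.testing.assert_array_equal(a[t].data, b[t].data)

    def test_single_layer_equals_manual_composition(self, tiny_graph):
        cfg = EncoderConfig(num_layers=1, d_model=16, num_heads=4)
        enc, _ = self.build(tiny_graph, cfg)
        g = tiny_graph.graph
        gv = g.with_reverse_relations()
        h0 = enc.project_input({t: gv.embeddings[t] for t in gv.nodes})
        h1 = enc.layers[0](h0, dict(gv.edges))
        from hgtlink.autodiff import relu
        manual = {t: relu(enc.head(h1[t])) for t in h1}
        auto = enc.encode(g)
        for t in auto:
            np.testing.assert_allclose(auto[t].data, manual[t].data, atol=1e-12)

    def test_permutation_equivariance(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        g = tiny_graph.graph
        feat = enc.encode(g)
        perm = np.random.default_rng(5).permutation(g.num_nodes("drug"))
        # rebuild the graph with drugs reordered
        new_order = [g.nodes["drug"][i] for i in perm]
        remap = {old: new for new, old in enumerate(perm)}
        nodes = dict(g.nodes)
        nodes["drug"] = new_order
        edges = {}
        for (st, rel, tt), arr in g.edges.items():
            arr = arr.copy()
            if st == "drug" and len(arr):
                arr[:, 0] = [remap[i] for i in arr[:, 0]]
            if tt == "drug" and len(arr):
                arr[:, 1] = [remap[i] for i in arr[:, 1]]
            edges[(st, rel, tt)] = arr
        emb = dict(g.embeddings)
        emb["drug"] = g.embeddings["drug"][perm]
        g2 = hl.HeteroGraph(nodes, edges, embeddings=emb)
        feat2 = enc.encode(g2)
        np.testing.assert_allclose(feat2["drug"].data, feat["drug"].data[perm], atol=1e-8)
        np.testing.assert_allclose(feat2["protein"].data, feat["protein"].data, atol=1e-8)

    def test_project_input_relu_clips_and_dropout_requires_rng(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        t = "drug"
        enc.input_proj[t].weight.data = np.eye(*enc.input_proj[t].weight.shape)
        enc.input_proj[t].bias.data[:] = 0.0
        x = np.full((1, enc.input_dims[t]), -3.0)
        out = enc.project_input({t: x})
        np.testing.assert_array_equal(out[t].data, 0.0)  # ReLU clips negatives
        with pytest.raises(ConfigurationError):
            enc.project_input({t: x}, train=True, rng=None)

    def test_input_dim_mismatch_names_type(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        with pytest.raises(ConfigurationError, match="drug"):
            enc.project_input({"drug": np.zeros((2, 3))})

    def test_unseen_relation_eval_raises_train_instantiates(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        layer = enc.layers[0]
        h = {"drug": Tensor(np.zeros((2, 16))), "disease": Tensor(np.zeros((2, 16)))}
        new_edges = {("drug", "brand_new", "disease"): np.array([[0, 0]])}
        with pytest.raises(UnseenRelationError):
            layer(h, new_edges, train=False)
        rng = np.random.Generator(np.random.PCG64(0))
        layer(h, new_edges, train=True, rng=rng)  # instantiated on the fly
        assert _tk(("drug", "brand_new", "disease")) in layer.w_att

    def test_mu_prior_initialized_to_one(self, tiny_graph):
        enc, _ = self.build(tiny_graph)
        for layer in enc.layers:
            for mu in layer.mu.values():
                np.testing.assert_array_equal(mu.data, [1.0])

    def test_d_model_must_divide_heads(self):
        with pytest.raises(ConfigurationError):
            EncoderConfig(num_layers=1, d_model=10, num_heads=4)
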