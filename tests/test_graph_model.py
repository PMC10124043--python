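"""Encodings, attention, layer semantics and training protocol of the classifier."""

import numpy as np
import pytest

from _oracles import dense_forward
from conftest import N_FEAT, path_graph, random_graph
from facin.graph_model import (
    DSBGNN,
    GraphTensors,
    ModelConfig,
    attention_coefficients,
    evaluate,
    loco_split,
    positional_encoding,
    train,
)


class TestPositionalEncoding:
    def test_position_zero(self):
        v = positional_encoding(0, 8)
        assert np.allclose(v[0::2], 0.0) and np.allclose(v[1::2], 1.0)

    def test_bounded_by_one(self):
        m = positional_encoding(np.arange(1000), 16)
        assert np.all(m >= -1.0) and np.all(m <= 1.0)

    def test_direct_formula(self):
        v = positional_encoding(1, 4)
        assert np.isclose(v[0], np.sin(1.0))
        assert np.isclose(v[1], np.cos(1.0))
        assert np.isclose(v[2], np.sin(1.0 / 10000 ** 0.5))

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(3, 5)


class TestCentralityEncoding:
    def test_equal_degrees_share_encoding(self):
        m = DSBGNN(ModelConfig(seed=1))
        assert np.array_equal(m.centrality_encoding(4), m.centrality_encoding(4))

    def test_degree_above_cap_maps_to_cap(self):
        cfg = ModelConfig(seed=1, degree_cap=8)
        m = DSBGNN(cfg)
        assert np.array_equal(m.centrality_encoding(100), m.centrality_encoding(8))
        assert not np.array_equal(m.centrality_encoding(7), m.centrality_encoding(8))

    def test_zero_degree_differs_from_connected(self):
        m = DSBGNN(ModelConfig(seed=1))
        assert not np.array_equal(m.centrality_encoding(0), m.centrality_encoding(3))


class TestAttentionCoefficients:
    rng = np.random.default_rng(5)
    d = 6
    W_N = rng.normal(size=(d, d))
    W_E = rng.normal(size=(d, d))
    beta = rng.normal(size=3 * d)

    def test_sum_to_one(self):
        h = self.rng.normal(size=self.d)
        nb = [self.rng.normal(size=self.d) for _ in range(4)]
        ef = [self.rng.normal(size=self.d) for _ in range(4)]
        a = attention_coefficients(h, nb, ef, self.beta, self.W_N, self.W_E)
        assert np.isclose(a.sum(), 1.0, atol=1e-6)

    def test_identical_neighbors_uniform(self):
        h = self.rng.normal(size=self.d)
        nb = [np.ones(self.d)] * 5
        ef = [np.full(self.d, 0.3)] * 5
        a = attention_coefficients(h, nb, ef, self.beta, self.W_N, self.W_E)
        assert np.allclose(a, 0.2)

    def test_two_neighbor_case_matches_scalar_arithmetic(self):
        # 1-dimensional hand-set parameters: direct evaluation of the rule
        h_i, h_j1, h_j2 = np.array([2.0]), np.array([1.0]), np.array([-1.0])
        e1, e2 = np.array([0.5]), np.array([1.5])
        W_N = np.array([[3.0]])
        W_E = np.array([[2.0]])
        beta = np.array([0.1, 0.4, -0.2])
        slope = 0.2

        def score(hj, he):
            s = 0.1 * 3 * 2 + 0.4 * 3 * hj[0] + (-0.2) * 2 * he[0]
            return s if s > 0 else slope * s

        s1, s2 = score(h_j1, e1), score(h_j2, e2)
        expected = np.exp([s1, s2]) / np.exp([s1, s2]).sum()
        got = attention_coefficients(h_i, [h_j1, h_j2], [e1, e2], beta, W_N, W_E, slope)
        assert np.allclose(got, expected)

    def test_empty_neighborhood(self):
        assert attention_coefficients(np.ones(3), [], [], self.beta, self.W_N, self.W_E).size == 0


class TestLayerAndReadout:
    @pytest.mark.parametrize("seed,n_heads", [(0, 1), (1, 2), (2, 2)])
    def test_forward_matches_dense_oracle(self, seed, n_heads):
        g = random_graph(n_nodes=6, seed=seed)
        model = DSBGNN(ModelConfig(seed=seed, n_heads=n_heads, hidden_dim=16))
        gt = GraphTensors.from_graph(g)
        states = []
        z = model.forward(gt, collect_states=states)
        ref_states, ref_probs, attn = dense_forward(model, g)
        for got, ref in zip(states, ref_states):
            np.testing.assert_allclose(got, ref, atol=1e-10)
        np.testing.assert_allclose(1 / (1 + np.exp(-z.data)), ref_probs, atol=1e-10)
        for alpha in attn.values():
            assert np.isclose(alpha.sum(), 1.0, atol=1e-6)

    def test_isolated_node_output_independent_of_others(self):
        g = random_graph(n_nodes=7, seed=3)
        g.edges = {e: w for e, w in g.edges.items() if 0 not in e}  # isolate node 0
        model = DSBGNN(ModelConfig(seed=0))
        p1 = model.predict_proba(g)
        g2 = random_graph(n_nodes=7, seed=3)
        g2.edges = dict(g.edges)
        g2.features = g.features.copy()
        g2.features[1:] = np.random.default_rng(9).random(g2.features[1:].shape)
        p2 = model.predict_proba(g2)
        assert np.isclose(p1[0], p2[0])

    def test_probabilities_in_unit_interval(self):
        g = random_graph(n_nodes=9, seed=4)
        p = DSBGNN(ModelConfig(seed=2)).predict_proba(g)
        assert np.all((p > 0) & (p < 1))

    def test_zero_readout_weights_give_half(self):
        g = random_graph(n_nodes=6, seed=1)
        model = DSBGNN(ModelConfig(seed=0))
        model.params["W_out"].data[:] = 0.0
        model.params["b_out"].data[:] = 0.0
        assert np.allclose(model.predict_proba(g), 0.5)

    def test_jk_readout_dimension_is_sum_of_layer_dims(self):
        cfg = ModelConfig(seed=0, hidden_dim=16, n_layers=3)
        model = DSBGNN(cfg)
        assert model.params["W_out"].shape == (16 * 3 + 16, 1)
        no_jk = DSBGNN(ModelConfig(seed=0, hidden_dim=16, n_layers=3, use_jk=False))
        assert no_jk.params["W_out"].shape == (16 + 16, 1)


class TestLocality:
    def test_far_node_perturbation_leaves_prediction_unchanged(self):
        # 3 layers -> prediction of node 0 depends on <= 3 hops
        g = path_graph(10, seed=0)
        model = DSBGNN(ModelConfig(seed=0))
        p_before = model.predict_proba(g)[0]
        g.features[5:] = np.random.default_rng(1).random(g.features[5:].shape)
        assert np.isclose(model.predict_proba(g)[0], p_before, atol=1e-12)

    def test_within_radius_perturbation_changes_prediction(self):
        g = path_graph(10, seed=0)
        model = DSBGNN(ModelConfig(seed=0))
        p_before = model.predict_proba(g)[0]
        g.features[2] = np.random.default_rng(2).random(N_FEAT)
        assert not np.isclose(model.predict_proba(g)[0], p_before, atol=1e-12)


class TestLocoSplit:
    CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]

    def test_21_training_chromosomes(self):
        train_c, val_c, test_c = loco_split(self.CHROMS, "chr1", "chr2")
        assert len(train_c) == 21 and val_c == ["chr2"] and test_c == ["chr1"]

    def test_partition_disjoint(self):
        train_c, val_c, test_c = loco_split(self.CHROMS, "chr5", "chrX")
        assert set(train_c).isdisjoint(val_c + test_c)
        assert sorted(train_c + val_c + test_c) == sorted(self.CHROMS)

    def test_every_chromosome_tested_once_over_folds(self):
        tested = [loco_split(self.CHROMS, t, "chr2" if t != "chr2" else "chr1")[2][0]
                  for t in self.CHROMS]
        assert sorted(tested) == sorted(self.CHROMS)

    def test_errors(self):
        with pytest.raises(ValueError):
            loco_split(self.CHROMS, "chr1", "chr1")
        with pytest.raises(ValueError):
            loco_split(self.CHROMS, "chr99", "chr1")


class TestTraining:
    def test_single_class_graph_rejected(self):
        g = random_graph(n_nodes=10, seed=0)
        g.labels = np.zeros(10, dtype=np.int64)
        with pytest.raises(ValueError):
            train([g], ModelConfig(epochs=1))

    def test_loss_non_increasing_moving_average(self, small_trained):
        model, *_ = small_trained
        loss = np.asarray(model.loss_history)
        k = 25
        ma = np.convolve(loss, np.ones(k) / k, mode="valid")
        assert ma[-1] < ma[0]
        assert np.all(np.diff(ma[:: len(ma) // 5 or 1]) < 0.05)

    def test_planted_rule_recovered_on_held_out_chromosome(self, small_trained):
        model, cfg, fx, graphs = small_trained
        _, auc = evaluate(model, graphs["c2"])
        assert auc > 0.8

    def test_save_load_round_trip(self, small_trained, tmp_path):
        model, cfg, fx, graphs = small_trained
        model.save(tmp_path / "m")
        clone = DSBGNN.load(tmp_path / "m")
        np.testing.assert_allclose(
            clone.predict_proba(graphs["c2"]), model.predict_proba(graphs["c2"]))

    def test_ablation_flags_change_predictions(self):
        g = random_graph(n_nodes=12, seed=6)
        base = DSBGNN(ModelConfig(seed=0)).predict_proba(g)
        for flag in ("use_kmer", "use_ctcf", "use_dnase", "zero_adjacency",
                     "use_jk", "use_positional", "use_centrality", "use_edge_encoding"):
            val = flag == "zero_adjacency"
            m = DSBGNN(ModelConfig(seed=0, **{flag: val}))
            assert m.predict_proba(g).shape == base.shape
            if flag not in ("use_jk",):  # JK changes readout shape, not comparably
                assert not np.allclose(m.predict_proba(g), base)
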