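"""Encoder, recurrent and decoder layers against independent oracles."""

import numpy as np
import pytest

from mdlink._autodiff import Tensor
from mdlink.data_io import AssociationMatrix
from mdlink.model import (
    MicrobeDiseaseGraphModel,
    ModelConfig,
    decode,
    forward,
    fuse,
    gat_attention,
    gat_layer,
    gcn_layer,
    init_state,
    lstm_step,
    sequence_forward,
)


def _rand_graph(rng, n):
    mask = rng.random((n, n)) > 0.5
    np.fill_diagonal(mask, True)
    norm_adj = rng.random((n, n)) * mask
    return mask, norm_adj


class TestModelConfig:
    def test_double_encoder_ablation_rejected(self):
        with pytest.raises(ValueError, match="both encoder"):
            ModelConfig(ablation={"no_gcn", "no_gat"})

    def test_unknown_flag_rejected(self):
        with pytest.raises(ValueError, match="unknown ablation"):
            ModelConfig(ablation={"no_decoder"})

    @pytest.mark.parametrize("kwargs", [
        {"embed_dim": 0}, {"num_layers": 0}, {"dropout_adj": 1.0},
        {"lstm_hidden": 3, "bidirectional": True},
    ])
    def test_invalid_hyperparameters(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestGcnLayer:
    def test_single_node_product(self):
        out = gcn_layer(Tensor([[2.0]]), Tensor([[1.0]]), Tensor([[3.0]]))
        assert out.data.tolist() == [[6.0]]

    def test_zero_weight_zero_output(self):
        out = gcn_layer(Tensor(np.ones((3, 2))), Tensor(np.eye(3)), Tensor(np.zeros((2, 2))))
        assert (out.data == 0).all()

    def test_matches_triple_product_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n, d, k = rng.integers(2, 9), rng.integers(1, 5), rng.integers(1, 5)
            h = rng.normal(size=(n, d))
            adj = rng.random((n, n))
            w = rng.normal(size=(d, k))
            out = gcn_layer(Tensor(h), Tensor(adj), Tensor(w)).data
            oracle = np.maximum(adj @ h @ w, 0.0)
            assert np.allclose(out, oracle, atol=1e-6)


def _gat_oracle(h, mask, w, a, slope):
    """Explicit per-edge softmax over each node's neighborhood."""
    n = h.shape[0]
    wh = h @ w
    k = wh.shape[1]
    alpha = np.zeros((n, n))
    for i in range(n):
        logits = {}
        for j in range(n):
            if mask[i, j]:
                z = float(a[:k, 0] @ wh[i] + a[k:, 0] @ wh[j])
                logits[j] = z if z > 0 else slope * z
        mx = max(logits.values())
        denom = sum(np.exp(v - mx) for v in logits.values())
        for j, v in logits.items():
            alpha[i, j] = np.exp(v - mx) / denom
    return alpha, wh


class TestGatLayers:
    def test_single_neighbor_gets_full_attention(self):
        h = Tensor(np.array([[1.0, 2.0], [0.5, 0.1]]))
        mask = np.array([[True, False], [True, True]])
        w = Tensor(np.eye(2))
        a = Tensor(np.ones((4, 1)))
        alpha, _ = gat_attention(h, mask, w, a)
        assert alpha.data[0, 0] == pytest.approx(1.0)

    def test_identical_neighbors_split_evenly(self):
        h = Tensor(np.ones((3, 2)))
        mask = np.ones((3, 3), dtype=bool)
        alpha, _ = gat_attention(h, mask, Tensor(np.eye(2)), Tensor(np.ones((4, 1))))
        assert np.allclose(alpha.data, 1 / 3)

    def test_rows_sum_to_one_and_respect_mask(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 8))
            mask, _ = _rand_graph(rng, n)
            h = rng.normal(size=(n, 3))
            alpha, _ = gat_attention(
                Tensor(h), mask, Tensor(rng.normal(size=(3, 4))), Tensor(rng.normal(size=(8, 1)))
            )
            assert np.allclose(alpha.data.sum(axis=1), 1.0, atol=1e-12)
            assert (alpha.data[~mask] == 0).all()

    def test_matches_per_edge_softmax_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(2, 7))
            mask, _ = _rand_graph(rng, n)
            h = rng.normal(size=(n, 3))
            w = rng.normal(size=(3, 2))
            a = rng.normal(size=(4, 1))
            alpha, wh = gat_attention(Tensor(h), mask, Tensor(w), Tensor(a), 0.2)
            o_alpha, o_wh = _gat_oracle(h, mask, w, a, 0.2)
            assert np.allclose(alpha.data, o_alpha, atol=1e-6)
            out = gat_layer(wh, alpha).data
            assert np.allclose(out, np.maximum(o_alpha @ o_wh, 0.0), atol=1e-6)

    def test_shared_neighbor_feature_ignores_attention(self):
        v = np.array([0.3, -0.7])
        h = Tensor(np.tile(v, (4, 1)))
        mask = np.ones((4, 4), dtype=bool)
        w = Tensor(np.array([[1.0, 0.5], [-0.2, 0.1]]))
        alpha, wh = gat_attention(h, mask, w, Tensor(np.ones((4, 1))))
        out = gat_layer(wh, alpha).data
        assert np.allclose(out, np.maximum(v @ w.data, 0.0))


class TestFuse:
    def test_concatenation(self):
        out = fuse(Tensor([[1.0]]), Tensor([[2.0]]))
        assert out.data.tolist() == [[1.0, 2.0]]

    def test_duplicate_halves_when_equal(self):
        h = Tensor(np.random.default_rng(0).normal(size=(3, 2)))
        out = fuse(h, h).data
        assert np.array_equal(out[:, :2], out[:, 2:])

    def test_single_channel_duplicated(self):
        h = Tensor(np.ones((2, 2)))
        out = fuse(None, h).data
        assert out.shape == (2, 4)
        assert np.array_equal(out[:, :2], out[:, 2:])

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse(Tensor(np.ones((2, 1))), Tensor(np.ones((3, 1))))


def _lstm_oracle(xs, w, u, b, hidden):
    """Scalar-loop LSTM reference (gate order i, f, o, c~)."""

    def sigmoid(z):
        return 1.0 / (1.0 + np.exp(-z))

    h = np.zeros(hidden)
    c = np.zeros(hidden)
    out = []
    for x in xs:
        z = x @ w + h @ u + b
        i, f, o, g = (z[:hidden], z[hidden:2*hidden], z[2*hidden:3*hidden], z[3*hidden:])
        i, f, o, g = sigmoid(i), sigmoid(f), sigmoid(o), np.tanh(g)
        c = f * c + i * g
        h = o * np.tanh(c)
        out.append(h.copy())
    return np.array(out)


class TestLstm:
    def test_zero_parameters_halve_gates(self):
        hidden = 3
        x = Tensor(np.ones((1, 2)))
        h0 = Tensor(np.zeros((1, hidden)))
        c0 = Tensor(np.full((1, hidden), 0.8))
        w = Tensor(np.zeros((2, 4 * hidden)))
        u = Tensor(np.zeros((hidden, 4 * hidden)))
        b = Tensor(np.zeros(4 * hidden))
        h1, c1 = lstm_step(x, h0, c0, w, u, b)
        assert np.allclose(c1.data, 0.4)           # f=0.5, c~=0
        assert np.allclose(h1.data, 0.5 * np.tanh(0.4))

    def test_zero_everything_gives_zero_state(self):
        hidden = 2
        zeros = lambda *s: Tensor(np.zeros(s))
        h1, c1 = lstm_step(
            zeros(1, 3), zeros(1, hidden), zeros(1, hidden),
            zeros(3, 4 * hidden), zeros(hidden, 4 * hidden), Tensor(np.zeros(4 * hidden)),
        )
        assert (h1.data == 0).all() and (c1.data == 0).all()

    def test_steps_match_scalar_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hidden, d, steps = 3, 4, int(rng.integers(1, 6))
            w = rng.normal(size=(d, 4 * hidden))
            u = rng.normal(size=(hidden, 4 * hidden))
            b = rng.normal(size=4 * hidden)
            xs = rng.normal(size=(steps, d))
            h = Tensor(np.zeros((1, hidden)))
            c = Tensor(np.zeros((1, hidden)))
            outs = []
            for t in range(steps):
                h, c = lstm_step(Tensor(xs[t:t+1]), h, c, Tensor(w), Tensor(u), Tensor(b))
                outs.append(h.data[0].copy())
            assert np.allclose(np.array(outs), _lstm_oracle(xs, w, u, b, hidden), atol=1e-10)

    def test_sequence_forward_unidirectional_matches_stepwise(self):
        rng = np.random.default_rng(4)
        config = ModelConfig(embed_dim=2, lstm_hidden=3, bidirectional=False, seed=0)
        state = init_state(config, 5, rng)
        xs = rng.normal(size=(6, 4))
        out = sequence_forward(Tensor(xs), state, bidirectional=False).data
        oracle = _lstm_oracle(
            xs, state["lstm_fwd_w"].data, state["lstm_fwd_u"].data,
            state["lstm_fwd_b"].data, 3,
        )
        assert np.allclose(out, oracle, atol=1e-10)

    def test_bidirectional_mirrors_on_palindromic_input(self):
        rng = np.random.default_rng(5)
        config = ModelConfig(embed_dim=2, lstm_hidden=6, bidirectional=True, seed=0)
        state = init_state(config, 5, rng)
        # force both directions to share parameters
        for suffix in ("w", "u", "b"):
            state[f"lstm_bwd_{suffix}"].data = state[f"lstm_fwd_{suffix}"].data.copy()
        half = rng.normal(size=(3, 4))
        xs = np.vstack([half, half[::-1]])
        out = sequence_forward(Tensor(xs), state, bidirectional=True).data
        fwd_part, bwd_part = out[:, :3], out[:, 3:]
        assert np.allclose(bwd_part, fwd_part[::-1], atol=1e-12)


class TestDecode:
    def test_orthogonal_embeddings_score_half(self):
        h = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]))
        out = decode(h, Tensor(np.eye(2)), Tensor(np.zeros(2)), 1)
        assert out.data[0, 0] == pytest.approx(0.5)

    def test_matched_embedding_with_ln3_norm(self):
        z = np.sqrt(np.log(3.0))
        h = Tensor(np.array([[z], [z]]))
        out = decode(h, Tensor(np.eye(1)), Tensor(np.zeros(1)), 1)
        assert out.data[0, 0] == pytest.approx(0.75)

    def test_scores_in_open_interval(self):
        rng = np.random.default_rng(6)
        h = Tensor(rng.normal(size=(7, 4)))
        out = decode(h, Tensor(rng.normal(size=(4, 3))), Tensor(rng.normal(size=3)), 4).data
        assert out.shape == (4, 3)
        assert ((out > 0) & (out < 1)).all()


def _tiny_model(ablation=frozenset(), seed=0):
    rng = np.random.default_rng(9)
    values = (rng.random((4, 3)) > 0.4).astype(int)
    values[0, 0] = 1
    adjacency = AssociationMatrix(
        values, {f"m{i}": i for i in range(4)}, {f"d{i}": i for i in range(3)}
    )
    config = ModelConfig(
        embed_dim=4, num_layers=2, lstm_hidden=4, seed=seed, ablation=ablation
    )
    return MicrobeDiseaseGraphModel(adjacency, config=config)


class TestForward:
    def test_inference_is_deterministic(self):
        model = _tiny_model()
        _, features, norm_adj, mask = model.build_graph()
        state = init_state(model.config, features.shape[1], np.random.default_rng(0))
        args = (features, norm_adj, mask, 4, model.config, state)
        s1, _ = forward(*args)
        s2, _ = forward(*args)
        assert np.array_equal(s1.data, s2.data)

    def test_fused_matrix_concatenates_channels(self):
        model = _tiny_model()
        _, features, norm_adj, mask = model.build_graph()
        state = init_state(model.config, features.shape[1], np.random.default_rng(0))
        _, enc = forward(features, norm_adj, mask, 4, model.config, state)
        assert np.array_equal(enc.h_fused, np.hstack([enc.h_gcn, enc.h_gat]))

    def test_no_lstm_ablation_skips_recurrent_stage(self):
        model = _tiny_model(ablation=frozenset({"no_lstm"}))
        _, features, norm_adj, mask = model.build_graph()
        state = init_state(model.config, features.shape[1], np.random.default_rng(0))
        scores, enc = forward(features, norm_adj, mask, 4, model.config, state)
        assert enc.h_lstm is None
        assert scores.data.shape == (4, 3)

    def test_end_to_end_matches_straightline_composition(self):
        """The orchestrated forward equals composing the layer functions."""
        model = _tiny_model()
        _, features, norm_adj, mask = model.build_graph()
        cfg = model.config
        state = init_state(cfg, features.shape[1], np.random.default_rng(0))
        scores, _ = forward(features, norm_adj, mask, 4, cfg, state)

        h_gcn = Tensor(features)
        for layer in range(cfg.num_layers):
            h_gcn = gcn_layer(h_gcn, Tensor(norm_adj), state[f"gcn{layer}_w"])
        h_gat = Tensor(features)
        for layer in range(cfg.num_layers):
            alpha, wh = gat_attention(
                h_gat, mask, state[f"gat{layer}_w"], state[f"gat{layer}_a"],
                cfg.leakyrelu_slope,
            )
            h_gat = gat_layer(wh, alpha)
        h_fused = fuse(h_gcn, h_gat)
        h_seq = sequence_forward(h_fused, state, cfg.bidirectional)
        expected = decode(h_seq, state["fc_w"], state["fc_b"], 4, state["fc_bias_b"])
        assert np.allclose(scores.data, expected.data, atol=1e-8)

    def test_encoder_permutation_equivariance(self):
        """GCN and GAT layers commute with a node relabeling."""
        rng = np.random.default_rng(10)
        n = 6
        mask, norm_adj = _rand_graph(rng, n)
        mask = mask | mask.T
        norm_adj = (norm_adj + norm_adj.T) / 2
        h = rng.normal(size=(n, 3))
        w = Tensor(rng.normal(size=(3, 2)))
        a = Tensor(rng.normal(size=(4, 1)))
        perm = rng.permutation(n)
        p = np.ix_(perm, perm)

        out = gcn_layer(Tensor(h), Tensor(norm_adj), w).data
        out_p = gcn_layer(Tensor(h[perm]), Tensor(norm_adj[p]), w).data
        assert np.allclose(out_p, out[perm], atol=1e-12)

        alpha, wh = gat_attention(Tensor(h), mask, w, a)
        gat_out = gat_layer(wh, alpha).data
        alpha_p, wh_p = gat_attention(Tensor(h[perm]), mask[p], w, a)
        gat_out_p = gat_layer(wh_p, alpha_p).data
        assert np.allclose(gat_out_p, gat_out[perm], atol=1e-12)
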