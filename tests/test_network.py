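"""Network components against independent brute-force oracles."""

import numpy as np
import pytest

from mbmstfnet.nn import (GRU, BiGRU, MBMSTFNet, ModelConfig,
                          MultiHeadAttention, softmax_cross_entropy)
from mbmstfnet.nn.gru import gru_cell_step

SMALL = ModelConfig(in_channels=3, conv_widths=(4, 6, 8), inception_out=8,
                    gru_hidden=6, gru_layers=2, n_heads=2, fc_dims=(10, 7),
                    n_classes=3, temporal_steps=4, dtype="float64", seed=3)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestGRUCell:
    def test_zero_fixed_point(self):
        h = gru_cell_step(np.zeros(4), np.zeros(3),
                          np.zeros((9, 4)), np.zeros((9, 3)), np.zeros(9))
        assert np.allclose(h, 0.0)

    def test_update_gate_saturation(self):
        """Huge update-gate bias drives h fully onto the candidate."""
        rng = np.random.default_rng(0)
        W = rng.standard_normal((9, 4))
        U = rng.standard_normal((9, 3))
        b = np.zeros(9)
        b[:3] = 50.0  # z -> 1
        x, h_prev = rng.standard_normal(4), rng.standard_normal(3)
        h = gru_cell_step(x, h_prev, W, U, b)
        r = _sigmoid(W[3:6] @ x + U[3:6] @ h_prev)
        g = np.tanh(W[6:] @ x + r * (U[6:] @ h_prev))
        assert np.allclose(h, g, atol=1e-12)

    def test_against_stepwise_oracle(self):
        """Gate-by-gate oracle with separate per-gate matrices, 1e-10."""
        rng = np.random.default_rng(7)
        H, D = 3, 5
        W = rng.standard_normal((3 * H, D))
        U = rng.standard_normal((3 * H, H))
        b = rng.standard_normal(3 * H)
        x = rng.standard_normal(D)
        h_prev = rng.standard_normal(H)

        Wz, Wr, Wh = W[:H], W[H:2 * H], W[2 * H:]
        Uz, Ur, Uh = U[:H], U[H:2 * H], U[2 * H:]
        bz, br, bh = b[:H], b[H:2 * H], b[2 * H:]
        z = _sigmoid(Wz @ x + Uz @ h_prev + bz)
        r = _sigmoid(Wr @ x + Ur @ h_prev + br)
        g = np.tanh(Wh @ x + r * (Uh @ h_prev) + bh)
        expected = (1 - z) * h_prev + z * g

        got = gru_cell_step(x, h_prev, W, U, b)
        assert np.allclose(got, expected, atol=1e-10)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            gru_cell_step(np.array([np.nan]), np.zeros(2),
                          np.zeros((6, 1)), np.zeros((6, 2)), np.zeros(6))


class TestGRUSequence:
    def test_forward_matches_cell_steps(self):
        gru = GRU(4, 3, rng=np.random.default_rng(1), dtype=np.float64)
        x = np.random.default_rng(2).standard_normal((2, 5, 4))
        out = gru.forward(x)
        h = np.zeros((2, 3))
        for t in range(5):
            h = gru_cell_step(x[:, t], h, gru.W.value, gru.U.value,
                              gru.b.value)
            assert np.allclose(out[:, t], h, atol=1e-10)

    def test_reversal_symmetry(self):
        """Backward GRU on x equals forward GRU on time-reversed x."""
        rng = np.random.default_rng(3)
        fwd = GRU(4, 3, reverse=False, rng=np.random.default_rng(5),
                  dtype=np.float64)
        bwd = GRU(4, 3, reverse=True, rng=np.random.default_rng(5),
                  dtype=np.float64)
        for p, q in zip(fwd.parameters(), bwd.parameters()):
            q.value[...] = p.value
        x = rng.standard_normal((2, 6, 4))
        assert np.allclose(bwd.forward(x), fwd.forward(x[:, ::-1])[:, ::-1],
                           atol=1e-12)

    def test_zero_everything_is_zero(self):
        gru = BiGRU(4, 3, dtype=np.float64)
        for p in gru.parameters():
            p.value[...] = 0.0
        assert np.allclose(gru.forward(np.zeros((2, 5, 4))), 0.0)


class TestAttention:
    def test_rows_stochastic(self):
        mha = MultiHeadAttention(8, 2, rng=np.random.default_rng(0),
                                 dtype=np.float64)
        mha.forward(np.random.default_rng(1).standard_normal((3, 8, 8)))
        assert np.allclose(mha.last_weights.sum(axis=-1), 1.0, atol=1e-12)

    def test_identical_tokens_give_uniform_weights(self):
        mha = MultiHeadAttention(8, 2, rng=np.random.default_rng(0),
                                 dtype=np.float64)
        token = np.random.default_rng(2).standard_normal(8)
        x = np.tile(token, (2, 8, 1))
        out = mha.forward(x)
        assert np.allclose(mha.last_weights, 1.0 / 8, atol=1e-12)
        assert np.allclose(out, out[:, :1, :], atol=1e-12)

    def test_against_brute_force_oracle(self):
        """Per-head score/softmax/weighted-sum oracle on a 2-step toy."""
        d_model, n_heads = 8, 2
        dk = d_model // n_heads
        mha = MultiHeadAttention(d_model, n_heads,
                                 rng=np.random.default_rng(4),
                                 dtype=np.float64)
        x = np.random.default_rng(5).standard_normal((1, 2, d_model))
        got = mha.forward(x)

        q_full = x[0] @ mha.Wq.value
        k_full = x[0] @ mha.Wk.value
        v_full = x[0] @ mha.Wv.value
        heads = []
        for i in range(n_heads):
            sl = slice(i * dk, (i + 1) * dk)
            q, k, v = q_full[:, sl], k_full[:, sl], v_full[:, sl]
            scores = q @ k.T / np.sqrt(dk)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            attn = e / e.sum(axis=1, keepdims=True)
            heads.append(attn @ v)
        expected = np.concatenate(heads, axis=1) @ mha.Wo.value
        assert np.allclose(got[0], expected, atol=1e-10)


class TestModelContracts:
    def test_forward_shapes_small_config(self):
        model = MBMSTFNet(SMALL)
        stages = {}
        x = np.random.default_rng(0).standard_normal((2, 4, 3, 8, 9))
        logits = model.forward(x, stages=stages)
        assert logits.shape == (2, 3)
        assert stages["conv1"][1] == (8, 4, 8, 9)
        assert stages["inception"][1] == (8, 8, 8, 9)
        assert stages["maxpool"][1] == (8, 8, 4, 4)
        assert stages["gru2"][1] == (2, 4, 12)
        assert stages["attention"][1] == (2, 4, 12)

    def test_conv_stack_nonnegative_and_zero_preserving(self):
        model = MBMSTFNet(SMALL)
        out = model.conv_stack_forward(np.zeros((2, 3, 8, 9)))
        assert np.allclose(out, 0.0)  # zero biases at init
        out2 = model.conv_stack_forward(
            np.random.default_rng(1).standard_normal((2, 3, 8, 9)))
        assert np.all(out2 >= 0)

    def test_pool_flatten_constant(self):
        model = MBMSTFNet(SMALL)
        flat = model.pool_flatten(np.full((2, 8, 8, 9), 3.5))
        assert flat.shape == (2, 8 * 4 * 4)
        assert np.allclose(flat, 3.5)

    def test_head_probabilities(self):
        model = MBMSTFNet(SMALL)
        x = np.random.default_rng(2).standard_normal((5, 4, 3, 8, 9))
        probs = model.predict_proba(x)
        assert probs.shape == (5, 3)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(probs >= 0)

    def test_zero_head_gives_uniform(self):
        model = MBMSTFNet(SMALL)
        model.out_layer.weight.value[...] = 0.0
        feats = np.random.default_rng(0).standard_normal((4, 12))
        from mbmstfnet.nn.layers import softmax

        probs = softmax(model.head_forward(feats))
        assert np.allclose(probs, 1.0 / 3, atol=1e-12)

    def test_batch_permutation_equivariance(self):
        model = MBMSTFNet(SMALL)
        x = np.random.default_rng(3).standard_normal((5, 4, 3, 8, 9))
        out = model.forward(x)
        perm = np.array([4, 2, 0, 1, 3])
        assert np.allclose(model.forward(x[perm]), out[perm], atol=1e-12)

    def test_deterministic_construction_and_forward(self):
        x = np.random.default_rng(4).standard_normal((2, 4, 3, 8, 9))
        a = MBMSTFNet(SMALL).forward(x)
        b = MBMSTFNet(SMALL).forward(x)
        assert np.array_equal(a, b)

    def test_inception_concat_order(self):
        model = MBMSTFNet(SMALL)
        x = np.abs(np.random.default_rng(5).standard_normal((2, 8, 8, 9)))
        full = model.inception.forward(x)
        alone = model.inception.branch_outputs(x)["1x1"]
        w = model.inception.width
        assert np.allclose(full[:, :w], alone, atol=1e-12)

    def test_checkpoint_round_trip(self, tmp_path):
        model = MBMSTFNet(SMALL)
        x = np.random.default_rng(6).standard_normal((2, 4, 3, 8, 9))
        before = model.forward(x)
        path = tmp_path / "model.npz"
        model.save(path)
        again = MBMSTFNet.load(path)
        assert np.array_equal(again.forward(x), before)
        assert again.config == SMALL

    def test_count_parameters_unknown_component(self):
        with pytest.raises(KeyError):
            MBMSTFNet(SMALL).count_parameters("bogus")

    def test_variant_configs(self):
        cfg = ModelConfig()
        assert cfg.variant("de_only").in_channels == 4
        assert cfg.variant("uni_gru").gru == "uni"
        assert cfg.variant("no_mha").mha is False
        assert cfg.variant("no_inception").inception is False
        with pytest.raises(KeyError):
            cfg.variant("nope")

    @pytest.mark.parametrize("variant,att_dim", [
        ("no_gru", 8 * 4 * 4),   # conv features feed attention directly
        ("no_mha", None),
        ("no_inception", None),
    ])
    def test_ablation_variants_forward(self, variant, att_dim):
        cfg = SMALL.variant(variant)
        model = MBMSTFNet(cfg)
        x = np.random.default_rng(1).standard_normal((2, 4, 3, 8, 9))
        stages = {}
        logits = model.forward(x, stages=stages)
        assert logits.shape == (2, 3)
        if variant == "no_gru":
            assert not model.grus
            assert stages["attention"][1] == (2, 4, att_dim)
        if variant == "no_mha":
            assert model.attention is None and "attention" not in stages
        if variant == "no_inception":
            assert model.inception is None and "inception" not in stages

    def test_uni_gru_step_dimension(self):
        model = MBMSTFNet(
            ModelConfig(**{**SMALL.__dict__, "gru": "uni"}))
        stages = {}
        model.forward(np.zeros((2, 4, 3, 8, 9)), stages=stages)
        assert stages["gru2"][1] == (2, 4, 6)  # single-direction width

    def test_divergence_guard_in_loss(self):
        logits = np.array([[1e30, -1e30]])
        loss, _ = softmax_cross_entropy(logits, np.array([1]))
        assert np.isfinite(loss) or loss > 0  # stays defined via log-eps
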