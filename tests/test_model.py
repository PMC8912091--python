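"""Network components against independent straight-line oracles, plus
gradient correctness, gating properties and checkpoint round trips."""

import numpy as np
import pytest

from bcsa import nn
from bcsa.model import (
    BCSARegressor,
    ModelConfig,
    channel_attention,
    fuse_and_pool,
    spatial_attention,
)

from .oracles import (
    ref_bilstm_encode,
    ref_channel_attention,
    ref_dense_head,
    ref_fuse_and_pool,
    ref_lstm,
    ref_spatial_attention,
)

RTOL = 1e-5


def random_instance(rng, T=None, H=None):
    T = T or int(rng.integers(2, 11))
    H = H or int(rng.integers(2, 9))
    return rng.normal(size=(T, H)), T, H


class TestOracleEquivalence:
    """Each stage matches a loop-based reference on random small instances."""

    @pytest.mark.parametrize("case", range(10))
    def test_lstm_recurrence(self, case):
        rng = np.random.default_rng(100 + case)
        T, D, H = int(rng.integers(2, 11)), int(rng.integers(2, 6)), int(
            rng.integers(2, 9)
        )
        x = rng.normal(size=(T, D))
        Wx = rng.normal(size=(D, 4 * H)) * 0.5
        Wh = rng.normal(size=(H, 4 * H)) * 0.5
        b = rng.normal(size=4 * H) * 0.5
        got, _ = nn.lstm_forward(x[None], Wx, Wh, b)
        np.testing.assert_allclose(got[0], ref_lstm(x, Wx, Wh, b), rtol=RTOL)

    @pytest.mark.parametrize("case", range(10))
    def test_bilstm_encode(self, case):
        rng = np.random.default_rng(200 + case)
        H = int(rng.integers(2, 9))
        config = ModelConfig(
            vocab_size=8, smiles_max_len=10, hidden_size=H,
            num_layers=int(rng.integers(1, 4)), dropout=0.0,
            mlp_hidden_size=4, embed_dim=3, channel_reduction=2,
            seed=case,
        )
        model = BCSARegressor(config)
        x = rng.normal(size=(int(rng.integers(2, 11)), 3))
        got = model.bilstm_encode(x)
        want = ref_bilstm_encode(x, model.params, config.num_layers, H)
        np.testing.assert_allclose(got, want, rtol=RTOL, atol=1e-12)

    @pytest.mark.parametrize("case", range(10))
    def test_channel_attention(self, case):
        rng = np.random.default_rng(300 + case)
        C, T, H = random_instance(rng)
        W0 = rng.normal(size=(H, max(1, H // 2)))
        W1 = rng.normal(size=(max(1, H // 2), H))
        got = channel_attention(C[None], W0, W1)[0]
        np.testing.assert_allclose(
            got, ref_channel_attention(C, W0, W1), rtol=RTOL, atol=1e-12
        )

    @pytest.mark.parametrize("case", range(10))
    def test_spatial_attention(self, case):
        rng = np.random.default_rng(400 + case)
        C, T, H = random_instance(rng)
        K1 = rng.normal(size=(7, H, 16))
        b1 = rng.normal(size=16)
        K2 = rng.normal(size=(7, 16, 1))
        b2 = rng.normal(size=1)
        got = spatial_attention(C[None], K1, b1, K2, b2)[0]
        np.testing.assert_allclose(
            got, ref_spatial_attention(C, K1, b1, K2, b2), rtol=RTOL, atol=1e-10
        )

    @pytest.mark.parametrize("case", range(10))
    def test_fuse_and_pool(self, case):
        rng = np.random.default_rng(500 + case)
        C, T, H = random_instance(rng)
        Mc = rng.normal(size=H)
        Ms = rng.normal(size=T)
        got = fuse_and_pool(C[None], Mc[None], Ms[None])[0]
        np.testing.assert_allclose(
            got, ref_fuse_and_pool(C, Mc, Ms), rtol=RTOL, atol=1e-12
        )

    @pytest.mark.parametrize("case", range(5))
    def test_dense_head(self, case, tiny_model):
        rng = np.random.default_rng(600 + case)
        O = rng.normal(size=tiny_model.config.hidden_size)
        p = tiny_model.params
        want = ref_dense_head(
            O, p["head_W1"], p["head_b1"], p["head_W2"], p["head_b2"]
        )
        np.testing.assert_allclose(tiny_model.predict_head(O), want, rtol=RTOL)


class TestClosedFormCases:
    def test_zero_channel_weights_give_zero_map(self, rng):
        C = rng.normal(size=(1, 6, 4))
        Mc = channel_attention(C, np.zeros((4, 2)), np.zeros((2, 4)))
        np.testing.assert_array_equal(Mc, 0.0)

    def test_constant_sequence_doubles_pooled_mlp(self, rng):
        # constant C makes Cavg == Cmax, so Mc = 2 * MLP(pooled)
        H = 4
        C = np.full((1, 5, H), 0.7)
        W0 = rng.normal(size=(H, 2))
        W1 = rng.normal(size=(2, H))
        Mc = channel_attention(C, W0, W1)
        single = nn.relu(np.full(H, 0.7) @ W0) @ W1
        np.testing.assert_allclose(Mc[0], 2 * single, rtol=RTOL)

    def test_zero_conv_weights_give_zero_spatial_map(self, rng):
        C = rng.normal(size=(1, 8, 4))
        Ms = spatial_attention(
            C, np.zeros((7, 4, 16)), np.zeros(16), np.zeros((7, 16, 1)),
            np.zeros(1),
        )
        np.testing.assert_array_equal(Ms, 0.0)
        assert Ms.shape == (1, 8)

    @pytest.mark.parametrize("n", [1, 2, 7, 20])
    def test_spatial_map_preserves_length(self, n, rng):
        C = rng.normal(size=(1, n, 3))
        K1 = rng.normal(size=(7, 3, 16))
        Ms = spatial_attention(C, K1, rng.normal(size=16),
                               rng.normal(size=(7, 16, 1)), rng.normal(size=1))
        assert Ms.shape == (1, n)

    def test_zero_maps_halve_the_sequence(self, rng):
        # sigma(0) = 0.5, so O = 0.5 * column mean of C exactly
        C = rng.normal(size=(1, 6, 5))
        O = fuse_and_pool(C, np.zeros((1, 5)), np.zeros((1, 6)))
        np.testing.assert_allclose(O, 0.5 * C.mean(axis=1), rtol=1e-12)

    def test_saturated_gate_approaches_column_mean(self, rng):
        C = rng.normal(size=(1, 6, 5))
        O = fuse_and_pool(C, np.full((1, 5), 50.0), np.full((1, 6), 50.0))
        np.testing.assert_allclose(O, C.mean(axis=1), rtol=1e-9)

    def test_gate_strictly_inside_unit_interval(self, rng):
        Mc = rng.normal(size=(2, 5)) * 10
        Ms = rng.normal(size=(2, 7)) * 10
        gate = nn.sigmoid(Mc[:, None, :] + Ms[:, :, None])
        assert np.all(gate > 0) and np.all(gate < 1)
        # consequently gating can only shrink magnitudes
        C = rng.normal(size=(2, 7, 5))
        assert np.all(np.abs(gate * C) <= np.abs(C))

    def test_zero_lstm_weights_give_zero_states(self):
        x = np.ones((1, 4, 3))
        hs, _ = nn.lstm_forward(
            x, np.zeros((3, 8)), np.zeros((2, 8)), np.zeros(8)
        )
        np.testing.assert_array_equal(hs, 0.0)

    def test_zero_head_weights_predict_zero(self, tiny_model):
        for key in ("head_W1", "head_b1", "head_W2", "head_b2"):
            tiny_model.params[key][:] = 0.0
        O = np.ones(tiny_model.config.hidden_size)
        assert tiny_model.predict_head(O) == 0.0


class TestForward:
    def test_shapes_through_pipeline(self, tiny_model, rng):
        cfg = tiny_model.config
        X = rng.integers(0, cfg.vocab_size, size=(3, cfg.smiles_max_len))
        M = tiny_model.embed(X[0])
        assert M.shape == (cfg.smiles_max_len, cfg.embed_dim)
        C = tiny_model.bilstm_encode(M)
        assert C.shape == (cfg.smiles_max_len, cfg.hidden_size)
        preds, cache = tiny_model.forward(X)
        assert preds.shape == (3,)
        assert cache["C"].shape == (3, cfg.smiles_max_len, cfg.hidden_size)
        assert cache["O"].shape == (3, cfg.hidden_size)

    def test_all_pad_input_embeds_pad_row(self, tiny_model):
        M = tiny_model.embed(np.zeros(6, dtype=np.int64))
        np.testing.assert_array_equal(M, np.tile(tiny_model.params["embed"][0], (6, 1)))

    def test_out_of_range_index_rejected(self, tiny_model):
        X = np.full((1, tiny_model.config.smiles_max_len), 99, dtype=np.int64)
        with pytest.raises(ValueError, match="vocab_size"):
            tiny_model.forward(X)

    def test_batching_consistency_and_permutation(self, tiny_model, rng):
        cfg = tiny_model.config
        X = rng.integers(0, cfg.vocab_size, size=(5, cfg.smiles_max_len))
        batch_preds = tiny_model.predict(X)
        single = np.array([tiny_model.predict(X[i : i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(batch_preds, single, rtol=1e-12)
        perm = rng.permutation(5)
        np.testing.assert_allclose(
            tiny_model.predict(X[perm]), batch_preds[perm], rtol=1e-12
        )

    def test_evaluation_mode_deterministic_despite_dropout(self, rng):
        config = ModelConfig(
            vocab_size=10, smiles_max_len=8, hidden_size=6, num_layers=2,
            dropout=0.5, mlp_hidden_size=4, channel_reduction=2, seed=0,
        )
        model = BCSARegressor(config)
        X = rng.integers(0, 10, size=(4, 8))
        np.testing.assert_array_equal(model.predict(X), model.predict(X))
        # training mode with dropout is stochastic
        a, _ = model.forward(X, training=True)
        b, _ = model.forward(X, training=True)
        assert not np.array_equal(a, b)

    def test_empty_batch_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.empty((0, 10), dtype=np.int64))


class TestGradients:
    def test_backward_matches_finite_differences(self, tiny_model, rng):
        """Analytic gradients of the full network agree with central
        differences on a random mini-batch."""
        model = tiny_model
        cfg = model.config
        X = rng.integers(0, cfg.vocab_size, size=(4, cfg.smiles_max_len))
        y = rng.normal(size=4)

        def loss():
            p, _ = model.forward(X)
            return float(np.mean((p - y) ** 2))

        preds, cache = model.forward(X)
        grads = model.backward(2.0 * (preds - y) / 4, cache)
        assert set(grads) == set(model.params)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for name, grad in grads.items():
            flat = model.params[name].ravel()
            for i in check_rng.choice(flat.size, size=min(4, flat.size),
                                      replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grad.ravel()[i]
                assert numeric == pytest.approx(analytic, rel=1e-3, abs=1e-7), name


class TestCheckpoint:
    def test_save_load_restores_bit_identical_predictions(
        self, tiny_model, rng, tmp_path
    ):
        cfg = tiny_model.config
        X = rng.integers(0, cfg.vocab_size, size=(3, cfg.smiles_max_len))
        path = tmp_path / "model.npz"
        tiny_model.save(path)
        restored, vocab = BCSARegressor.load(path)
        assert vocab is None
        assert restored.config == cfg
        np.testing.assert_array_equal(
            restored.predict(X), tiny_model.predict(X)
        )

    def test_vocab_embedded_in_checkpoint(self, tiny_model, tmp_path):
        from bcsa.tokenizer import Vocabulary

        vocab = Vocabulary({"<pad>": 0, "<unk>": 1, "C": 2})
        path = tmp_path / "model.npz"
        tiny_model.save(path, vocab=vocab)
        _, restored = BCSARegressor.load(path)
        assert restored.token_to_index == vocab.token_to_index


class TestModelConfig:
    def test_embed_dim_defaults_to_hidden_size(self):
        assert ModelConfig(hidden_size=48, embed_dim=None).embed_dim == 48

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dropout": 1.0},
            {"dropout": -0.1},
            {"hidden_size": 0},
            {"learning_rate": 0.0},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)
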