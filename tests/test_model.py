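"""Attention oracles, positional encoding closed forms, encoder behaviour,
branch geometry and variant heads."""

import math

import numpy as np
import pytest

from sttcnn.model import (ModelConfig, branch_forward, encoder_block,
                          forward_logits, init_params, load_checkpoint,
                          multi_head_attention, parameter_count,
                          positional_encoding, predict, save_checkpoint,
                          scaled_dot_product_attention, standardize_segments)
from sttcnn.autodiff import Tensor


# -- independent oracles -----------------------------------------------------

def attention_oracle(Q, K, V, d_k):
    """Element-by-element softmax attention: explicit exp / normalize loops."""
    n, m = Q.shape[0], K.shape[0]
    out = np.zeros((n, V.shape[1]))
    weights = np.zeros((n, m))
    for i in range(n):
        scores = [sum(Q[i, t] * K[j, t] for t in range(Q.shape[1])) / math.sqrt(d_k)
                  for j in range(m)]
        mx = max(scores)
        exps = [math.exp(s - mx) for s in scores]
        z = sum(exps)
        for j in range(m):
            weights[i, j] = exps[j] / z
            out[i] += weights[i, j] * V[j]
    return out, weights


def mha_oracle(X, params, h):
    """Per-head loop + concat + output projection, built on the loop oracle."""
    d = X.shape[1]
    d_k = d // h
    heads = []
    for j in range(h):
        sl = slice(j * d_k, (j + 1) * d_k)
        Q = X @ params["Wq"][:, sl] + params["bq"][sl]
        K = X @ params["Wk"][:, sl] + params["bk"][sl]
        V = X @ params["Wv"][:, sl] + params["bv"][sl]
        heads.append(attention_oracle(Q, K, V, d_k)[0])
    return np.concatenate(heads, axis=1) @ params["Wo"] + params["bo"]


def random_mha_params(rng, d):
    p = {}
    for k in ("Wq", "Wk", "Wv", "Wo"):
        p[k] = rng.standard_normal((d, d)) * 0.3
    for k in ("bq", "bk", "bv", "bo"):
        p[k] = rng.standard_normal(d) * 0.1
    return p


class TestPositionalEncoding:
    def test_position_zero_is_sin0_cos0(self):
        t = positional_encoding(16, 8).table
        np.testing.assert_array_equal(t[0, 0::2], 0.0)
        np.testing.assert_array_equal(t[0, 1::2], 1.0)

    def test_closed_form_value(self):
        # pos=1, d=4, i=0 -> sin(1)
        t = positional_encoding(4, 4).table
        assert t[1, 0] == pytest.approx(math.sin(1.0), abs=1e-12)
        assert t[1, 1] == pytest.approx(math.cos(1.0), abs=1e-12)
        # i=1: wavelength 10000^(2/4)
        assert t[1, 2] == pytest.approx(math.sin(1.0 / 100.0), abs=1e-12)

    def test_unit_circle_identity(self):
        t = positional_encoding(600, 64).table
        pairs = t[:, 0::2] ** 2 + t[:, 1::2] ** 2
        np.testing.assert_allclose(pairs, 1.0, atol=1e-9)
        assert np.all(np.abs(t) <= 1.0)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 7)


class TestScaledDotProductAttention:
    def test_single_key_passes_value_through(self):
        res = scaled_dot_product_attention([[1.0]], [[1.0]], [[2.0]], d_k=1)
        np.testing.assert_allclose(res.output, [[2.0]])
        np.testing.assert_allclose(res.weights, [[1.0]])

    def test_identical_keys_average_values(self):
        K = [[1.0, 0.0], [1.0, 0.0]]
        V = [[2.0, 0.0], [4.0, 6.0]]
        res = scaled_dot_product_attention([[3.0, 1.0]], K, V)
        np.testing.assert_allclose(res.output, [[3.0, 3.0]], atol=1e-12)

    def test_matches_loop_oracle(self, rng):
        Q, K = rng.standard_normal((3, 4)), rng.standard_normal((5, 4))
        V = rng.standard_normal((5, 2))
        res = scaled_dot_product_attention(Q, K, V)
        out, w = attention_oracle(Q, K, V, 4)
        np.testing.assert_allclose(res.output, out, atol=1e-6)
        np.testing.assert_allclose(res.weights, w, atol=1e-6)

    def test_weights_row_stochastic(self, rng):
        res = scaled_dot_product_attention(rng.standard_normal((6, 3)) * 5,
                                           rng.standard_normal((7, 3)) * 5,
                                           rng.standard_normal((7, 4)))
        assert np.all(res.weights >= 0)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-6)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            scaled_dot_product_attention(rng.standard_normal((3, 4)),
                                         rng.standard_normal((5, 3)),
                                         rng.standard_normal((5, 2)))


class TestMultiHeadAttention:
    @pytest.mark.parametrize("h,seq,d", [(8, 8, 16), (4, 5, 8), (2, 7, 16)])
    def test_matches_per_head_loop_oracle(self, rng, h, seq, d):
        X = rng.standard_normal((seq, d))
        params = random_mha_params(rng, d)
        got = multi_head_attention(X, params, h)
        want = mha_oracle(X, params, h)
        np.testing.assert_allclose(got, want, atol=1e-6)
        assert got.shape == X.shape

    def test_single_head_identity_projection(self, rng):
        d = 6
        X = rng.standard_normal((4, d))
        params = random_mha_params(rng, d)
        params["Wo"] = np.eye(d)
        params["bo"] = np.zeros(d)
        got = multi_head_attention(X, params, h=1)
        res = scaled_dot_product_attention(X @ params["Wq"] + params["bq"],
                                           X @ params["Wk"] + params["bk"],
                                           X @ params["Wv"] + params["bv"])
        np.testing.assert_allclose(got, res.output, atol=1e-10)

    def test_indivisible_heads_rejected(self, rng):
        with pytest.raises(ValueError):
            multi_head_attention(rng.standard_normal((4, 6)),
                                 random_mha_params(rng, 6), h=4)


class TestEncoderBlock:
    def _cfg(self, **kw):
        return ModelConfig(n_channels=4, window_samples=10, n_classes=2,
                           d_model=8, n_heads=2, dropout=0.0, **kw)

    def _block_params(self, rng, cfg):
        params = init_params(cfg, seed=3)
        return {name.rsplit(".", 1)[-1]: t.data for name, t in params.items()
                if name.startswith("s.enc0.")}

    def test_eval_mode_deterministic(self, rng):
        cfg = self._cfg()
        p = self._block_params(rng, cfg)
        X = rng.standard_normal((6, 8))
        np.testing.assert_array_equal(encoder_block(X, cfg, p),
                                      encoder_block(X, cfg, p))

    def test_zero_sublayers_reduce_to_stacked_layernorm(self, rng):
        cfg = self._cfg()
        p = self._block_params(rng, cfg)
        for k in ("Wq", "Wk", "Wv", "Wo", "W1", "W2", "bq", "bk", "bv",
                  "bo", "b1", "b2"):
            p[k] = np.zeros_like(p[k])
        X = rng.standard_normal((5, 8))
        got = encoder_block(X, cfg, p)

        def ln(a, eps=1e-5):
            mu = a.mean(-1, keepdims=True)
            return (a - mu) / np.sqrt(((a - mu) ** 2).mean(-1, keepdims=True) + eps)

        np.testing.assert_allclose(got, ln(ln(X)), atol=1e-10)

    def test_layernorm_rows_standardized(self, rng):
        cfg = self._cfg()
        p = self._block_params(rng, cfg)
        # identity affine so the raw normalisation is observable
        p["ln1_g"] = np.ones(8); p["ln1_b"] = np.zeros(8)
        p["ln2_g"] = np.ones(8); p["ln2_b"] = np.zeros(8)
        out = encoder_block(rng.standard_normal((6, 8)), cfg, p)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-4)
        np.testing.assert_allclose(out.var(axis=1), 1.0, atol=1e-3)

    def test_nonfinite_input_rejected(self, rng):
        cfg = self._cfg()
        p = self._block_params(rng, cfg)
        X = np.full((3, 8), np.nan)
        with pytest.raises(ValueError, match="finite"):
            encoder_block(X, cfg, p)


class TestBranches:
    def test_seed_scale_sequence_lengths(self):
        cfg = ModelConfig(n_channels=62, window_samples=600, n_classes=3)
        assert cfg.seq_len("spatial") == 62
        assert cfg.seq_len("temporal") == 600
        assert cfg.token_features("spatial") == 600
        assert cfg.token_features("temporal") == 62

    def test_branch_output_shapes(self, rng):
        cfg = ModelConfig(n_channels=6, window_samples=20, n_classes=3,
                          d_model=8, n_heads=2)
        params = {k: v.data for k, v in init_params(cfg, seed=0).items()}
        X = rng.standard_normal((3, 6, 20))
        assert branch_forward(X, "spatial", cfg, params).shape == (3, 6, 8)
        assert branch_forward(X, "temporal", cfg, params).shape == (3, 20, 8)

    def test_channel_permutation_equivariance_without_pe(self, rng):
        cfg = ModelConfig(n_channels=6, window_samples=20, n_classes=3,
                          d_model=8, n_heads=2, use_positional_encoding=False,
                          input_standardize=False)
        params = {k: v.data for k, v in init_params(cfg, seed=0).items()}
        X = rng.standard_normal((2, 6, 20))
        perm = rng.permutation(6)
        out = branch_forward(X, "spatial", cfg, params)
        out_perm = branch_forward(X[:, perm, :], "spatial", cfg, params)
        np.testing.assert_allclose(out_perm, out[:, perm, :], atol=1e-5)

    def test_positional_encoding_breaks_permutation_symmetry(self, rng):
        cfg = ModelConfig(n_channels=6, window_samples=20, n_classes=3,
                          d_model=8, n_heads=2, use_positional_encoding=True,
                          input_standardize=False)
        params = {k: v.data for k, v in init_params(cfg, seed=0).items()}
        X = rng.standard_normal((2, 6, 20))
        perm = np.array([1, 0, 3, 2, 5, 4])
        out = branch_forward(X, "spatial", cfg, params)
        out_perm = branch_forward(X[:, perm, :], "spatial", cfg, params)
        assert np.max(np.abs(out_perm - out[:, perm, :])) > 1e-3


class TestPredict:
    @pytest.mark.parametrize("variant,n_classes", [
        ("st-tcnn", 3), ("st-t", 3), ("s-t", 2), ("t-t", 4),
    ])
    def test_probability_rows(self, rng, variant, n_classes):
        cfg = ModelConfig(n_channels=5, window_samples=16, n_classes=n_classes,
                          variant=variant, d_model=8, n_heads=2, conv_channels=4)
        params = init_params(cfg, seed=1)
        probs = predict(rng.standard_normal((7, 5, 16)), cfg, params)
        assert probs.shape == (7, n_classes)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_fc_weights_give_uniform(self, rng):
        cfg = ModelConfig(n_channels=5, window_samples=16, n_classes=3,
                          d_model=8, n_heads=2, conv_channels=4)
        params = init_params(cfg, seed=1)
        params["head.fc.W"].data[:] = 0.0
        params["head.fc.b"].data[:] = 0.0
        probs = predict(rng.standard_normal((4, 5, 16)), cfg, params)
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-12)

    def test_train_mode_reproducible_with_seeded_rng(self, rng):
        cfg = ModelConfig(n_channels=5, window_samples=16, n_classes=3,
                          d_model=8, n_heads=2, conv_channels=4, dropout=0.3)
        params = init_params(cfg, seed=1)
        X = rng.standard_normal((4, 5, 16))
        a = predict(X, cfg, params, mode="train", rng=np.random.default_rng(9))
        b = predict(X, cfg, params, mode="train", rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)
        c = predict(X, cfg, params, mode="train", rng=np.random.default_rng(10))
        assert np.max(np.abs(a - c)) > 0


class TestConfigAndCheckpoint:
    def test_parameter_count_pure_function_of_config(self):
        cfg = ModelConfig(n_channels=8, window_samples=64, n_classes=3,
                          d_model=16, n_heads=8, conv_channels=8)
        # frozen regression value; hand-tallied: embeddings 1040+144,
        # 2 encoder blocks of 3280, conv head 80+584, FC 2304*3+3
        total = sum(t.data.size for t in init_params(cfg, seed=42).values())
        assert parameter_count(cfg) == total == 15323

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_channels=4, window_samples=8, n_classes=2,
                        d_model=10, n_heads=4)
        with pytest.raises(ValueError, match="variant"):
            ModelConfig(n_channels=4, window_samples=8, n_classes=2,
                        variant="cnn-only")

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        cfg = ModelConfig(n_channels=5, window_samples=16, n_classes=3,
                          d_model=8, n_heads=2, conv_channels=4)
        params = init_params(cfg, seed=5)
        save_checkpoint(tmp_path / "m.npz", cfg, params)
        cfg2, params2 = load_checkpoint(tmp_path / "m.npz")
        assert cfg2 == cfg
        X = rng.standard_normal((3, 5, 16))
        np.testing.assert_array_equal(predict(X, cfg, params),
                                      predict(X, cfg2, params2))


def test_standardize_segments_zero_mean_unit_variance(rng):
    X = rng.standard_normal((4, 3, 50)) * 40 + 7
    Z = standardize_segments(X)
    np.testing.assert_allclose(Z.mean(axis=-1), 0.0, atol=1e-10)
    np.testing.assert_allclose(Z.std(axis=-1), 1.0, atol=1e-6)
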