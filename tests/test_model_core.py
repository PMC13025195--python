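"""Architecture components: positional encoding, multi-scale CNN, partial
convolution, IFFN, encoder blocks, classifier head."""

import numpy as np
import pytest
from scipy.stats import norm

from ictd.autodiff import Tensor, no_grad
from ictd.layers import conv1d
from ictd.model import (ICTDModel, IFFN, EncoderBlock, ModelConfig,
                        MultiScaleCNNBranch, PartialConv, PlainFFN, classify,
                        multiscale_matrix, partial_conv, positional_encoding)


def gelu_exact(x):
    x = np.asarray(x, dtype=float)
    return x * norm.cdf(x)


class TestPositionalEncoding:
    def test_position_zero_rows(self):
        pe = positional_encoding(4, 6)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_first_pair_at_position_one(self):
        pe = positional_encoding(2, 4)
        assert pe[1, 0] == pytest.approx(np.sin(1.0))
        assert pe[1, 1] == pytest.approx(np.cos(1.0))
        assert pe[1, 2] == pytest.approx(np.sin(1.0 / 100.0))
        assert pe[1, 3] == pytest.approx(np.cos(1.0 / 100.0))

    def test_pythagorean_identity_everywhere(self):
        pe = positional_encoding(50, 16)
        np.testing.assert_allclose(pe[:, 0::2] ** 2 + pe[:, 1::2] ** 2, 1.0,
                                   atol=1e-12)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(10, 5)


class TestMultiScale:
    def test_matrix_matches_bruteforce_pool_then_upsample(self):
        T, kernels = 7, (2, 3)
        m = multiscale_matrix(T, kernels)
        x = np.random.default_rng(0).normal(size=T)
        maps = [x.copy()]
        for k in kernels:
            up = np.empty(T)
            for a in range(0, T, k):
                b = min(a + k, T)
                up[a:b] = x[a:b].mean()
            maps.append(up)
        np.testing.assert_allclose(m @ x, np.mean(maps, axis=0), atol=1e-12)

    def test_merge_is_identity_on_constant_maps(self):
        # pooled copies of a time-constant map all equal the map, so the
        # multi-scale average leaves it unchanged (rows sum to 1)
        for T in (1, 5, 20, 600):
            m = multiscale_matrix(T)
            np.testing.assert_allclose(m @ np.ones(T), 1.0, atol=1e-12)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)

    def test_output_shape_128_channels_preserved_timesteps(self, rng):
        cfg = ModelConfig(in_channels=5)
        branch = MultiScaleCNNBranch(cfg, rng)
        with no_grad():
            out = branch(Tensor(np.random.default_rng(0).normal(size=(2, 5, 600))))
        assert out.shape == (2, 128, 600)

    def test_single_timestep_equals_conv_stack(self, rng):
        cfg = ModelConfig(in_channels=4)
        branch = MultiScaleCNNBranch(cfg, rng)
        x = Tensor(np.random.default_rng(1).normal(size=(3, 4, 1)))
        with no_grad():
            out = branch(x)
            conv_only = branch.conv2(branch.conv1(x).relu()).relu()
        np.testing.assert_allclose(out.data, conv_only.data, atol=1e-12)

    def test_channel_mismatch_rejected(self, rng):
        branch = MultiScaleCNNBranch(ModelConfig(in_channels=5), rng)
        with pytest.raises(ValueError):
            branch(Tensor(np.zeros((1, 3, 10))))

    def test_concat_merge_keeps_shape(self, rng):
        cfg = ModelConfig(in_channels=3, merge_mode="concat")
        branch = MultiScaleCNNBranch(cfg, rng)
        with no_grad():
            out = branch(Tensor(np.random.default_rng(0).normal(size=(2, 3, 12))))
        assert out.shape == (2, 128, 12)


class TestPartialConv:
    def test_full_ratio_equals_ordinary_convolution(self, rng):
        x = Tensor(rng.normal(size=(2, 4, 6)))
        w = Tensor(rng.normal(size=(4, 4, 3)))
        b = Tensor(rng.normal(size=4))
        with no_grad():
            np.testing.assert_array_equal(
                partial_conv(x, w, b, ratio=1.0).data,
                conv1d(x, w, b).data)

    def test_untouched_channels_bit_identical(self, rng):
        x = Tensor(rng.normal(size=(2, 128, 4)))
        w = Tensor(rng.normal(size=(32, 32, 3)))
        with no_grad():
            out = partial_conv(x, w, None, ratio=0.25)
        np.testing.assert_array_equal(out.data[:, 32:, :], x.data[:, 32:, :])

    def test_identity_kernel_reproduces_input(self):
        x = Tensor(np.random.default_rng(0).normal(size=(1, 1, 8)))
        w = Tensor(np.array([[[0.0, 1.0, 0.0]]]))
        with no_grad():
            out = partial_conv(x, w, None, ratio=1.0,
                               mask=np.ones((1, 8), bool))
        np.testing.assert_allclose(out.data, x.data, atol=1e-12)

    def test_oversized_kernel_rejected(self):
        x = Tensor(np.zeros((1, 2, 2)))
        w = Tensor(np.zeros((2, 2, 5)))
        with pytest.raises(ValueError):
            partial_conv(x, w, None, ratio=1.0)

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            partial_conv(Tensor(np.zeros((1, 2, 4))),
                         Tensor(np.zeros((2, 2, 3))), None, ratio=0.0)


class TestIFFN:
    def test_zero_input_zero_biases_gives_zero_output(self, rng):
        cfg = ModelConfig(dropout=0.0)
        iffn = IFFN(128, cfg, rng)
        iffn.eval()
        # weights are random but every bias is zero-initialised
        with no_grad():
            out = iffn(Tensor(np.zeros((2, 3, 128))))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_shape_preserved(self, rng):
        iffn = IFFN(128, ModelConfig(dropout=0.0), rng)
        iffn.eval()
        with no_grad():
            out = iffn(Tensor(rng.normal(size=(2, 5, 128))))
        assert out.shape == (2, 5, 128)

    def test_hand_evaluation_with_identity_weights(self, rng):
        """d=4, T=1, identity W1/W2 and identity convolutions, input of ones:
        u = GELU(1); r = u^2 gated halves; output = GELU((u^2,u^2,u,u))."""
        cfg = ModelConfig(dropout=0.0, pconv_ratio=0.5, gate_kernel=3)
        iffn = IFFN(4, cfg, rng)
        iffn.eval()
        iffn.w1.w.data = np.eye(4)
        iffn.w1.b.data[:] = 0
        iffn.w2.w.data = np.eye(4)
        iffn.w2.b.data[:] = 0
        # pconv touches channels 0..1: make it the identity kernel
        iffn.pconv.conv.w.data = np.zeros((2, 2, 3))
        iffn.pconv.conv.w.data[0, 0, 1] = 1.0
        iffn.pconv.conv.w.data[1, 1, 1] = 1.0
        iffn.pconv.conv.b.data[:] = 0
        iffn.gate.w.data = np.zeros((2, 3))
        iffn.gate.w.data[:, 1] = 1.0
        iffn.gate.b.data[:] = 0
        with no_grad():
            out = iffn(Tensor(np.ones((1, 1, 4))))
        g = gelu_exact(1.0)
        expected = gelu_exact([g * g, g * g, g, g])
        np.testing.assert_allclose(out.data[0, 0], expected, atol=1e-12)

    def test_odd_width_rejected(self, rng):
        with pytest.raises(ValueError):
            IFFN(127, ModelConfig(), rng)

    def test_autoencoder_bottleneck_path_runs(self, rng):
        cfg = ModelConfig(dropout=0.0, iffn_autoencoder=True)
        iffn = IFFN(128, cfg, rng)
        iffn.eval()
        with no_grad():
            out = iffn(Tensor(rng.normal(size=(1, 2, 128))))
        assert out.shape == (1, 2, 128)

    def test_narrow_w2_variant_preserves_shape(self, rng):
        cfg = ModelConfig(dropout=0.0, iffn_wide_w2=False)
        iffn = IFFN(128, cfg, rng)
        iffn.eval()
        with no_grad():
            out = iffn(Tensor(rng.normal(size=(1, 2, 128))))
        assert out.shape == (1, 2, 128)


class TestEncoderBlock:
    def test_eval_mode_is_deterministic(self, rng):
        blk = EncoderBlock(128, ModelConfig(), rng)
        blk.eval()
        x = Tensor(rng.normal(size=(2, 3, 128)))
        with no_grad():
            a = blk(x).data
            b = blk(x).data
        np.testing.assert_array_equal(a, b)

    def test_shape_preserved(self, rng):
        blk = EncoderBlock(128, ModelConfig(dropout=0.0), rng)
        blk.eval()
        with no_grad():
            out = blk(Tensor(rng.normal(size=(2, 7, 128))))
        assert out.shape == (2, 7, 128)

    def test_attention_sublayer_permutation_equivariant_without_positions(
            self, rng):
        # self-attention carries no order information of its own; only the
        # positional encoding (and the IFFN's temporal convolutions) do
        blk = EncoderBlock(128, ModelConfig(dropout=0.0), rng)
        blk.eval()
        x = rng.normal(size=(1, 3, 128))
        perm = [2, 0, 1]
        with no_grad():
            a = blk.ln1(Tensor(x) + blk.attn(Tensor(x))).data
            b = blk.ln1(Tensor(x[:, perm, :])
                        + blk.attn(Tensor(x[:, perm, :]))).data
        np.testing.assert_allclose(a[:, perm, :], b, atol=1e-9)

    def test_head_divisibility_enforced(self, rng):
        with pytest.raises(ValueError):
            ModelConfig(conv2_out=130)


class TestClassify:
    def test_equal_logits_uniform(self):
        probs = classify(np.zeros((3, 4)), np.eye(4))
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_extreme_logits_stable(self):
        probs = classify(np.array([[1000.0, 0.0]]), np.eye(2))
        assert np.all(np.isfinite(probs))
        assert probs[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_worked_softmax_values(self):
        probs = classify(np.array([[1.0, 2.0, 3.0]]), np.eye(3))
        np.testing.assert_allclose(probs[0], [0.09003057, 0.24472847, 0.66524096],
                                   atol=1e-7)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            classify(np.zeros((2, 3)), np.zeros((3, 1)))


class TestWholeModel:
    def test_parameter_count_deterministic(self):
        m1 = ICTDModel((6, 3), 4, seed=0)
        m2 = ICTDModel((6, 3), 4, seed=0)
        assert m1.n_parameters() == m2.n_parameters()
        for p, q in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_forward_shapes(self, rng):
        model = ICTDModel((6, 3), 4, seed=1)
        model.eval()
        x1 = rng.normal(size=(5, 6))
        x2 = rng.normal(size=(5, 3))
        with no_grad():
            logits, h1, h2 = model.forward(x1, x2)
        assert logits.shape == (5, 4)
        assert h1.shape == (5, model.cfg.proj_dim)
        assert h1.shape == h2.shape

    def test_plain_ffn_variant_constructs_and_runs(self, rng):
        cfg = ModelConfig(use_iffn=False, dropout=0.0)
        model = ICTDModel((4, 3), 3, cfg=cfg, seed=2)
        model.eval()
        with no_grad():
            logits, _, _ = model.forward(rng.normal(size=(4, 4)),
                                         rng.normal(size=(4, 3)))
        assert logits.shape == (4, 3)
        assert isinstance(model.encoder1[0].ffn, PlainFFN)

    def test_probabilities_row_stochastic(self, rng):
        model = ICTDModel((4, 3), 5, seed=3)
        probs = model.predict_proba(rng.normal(size=(6, 4)),
                                    rng.normal(size=(6, 3)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
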