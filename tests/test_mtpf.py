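"""Texture priors (Laplacian / LBP / Gabor), compression, attention fusion,
pyramid pooling and the MMD constraint."""

import numpy as np
import pytest

from oracles import lbp_reference, mmd_double_sum
from kidneyct._autodiff import Tensor
from kidneyct.mtpf import (LAPLACIAN_KERNEL, AttentionFusion, GaborBankConfig,
                           MMDConfig, PriorCompressor, attention_fuse,
                           build_prior_stack, compress_priors,
                           gabor_bank_responses, gabor_kernel, laplacian_edge,
                           lbp_encode, mmd_loss, pyramid_pool)


class TestLaplacianEdge:
    def test_kernel_entries(self):
        np.testing.assert_array_equal(
            LAPLACIAN_KERNEL,
            np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=float))

    def test_constant_image_gives_zero(self):
        np.testing.assert_allclose(laplacian_edge(np.full((8, 8), 0.37)), 0.0,
                                   atol=1e-14)

    def test_unit_impulse_response(self):
        img = np.zeros((7, 7))
        img[3, 3] = 1.0
        edge = laplacian_edge(img)
        assert edge[3, 3] == 4.0
        for dy, dx in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
            assert edge[3 + dy, 3 + dx] == -1.0
        assert edge[2, 2] == 0.0 and edge[4, 4] == 0.0
        assert np.count_nonzero(edge) == 5

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            laplacian_edge(np.zeros((2, 5)))


class TestLBP:
    def test_constant_image_all_ties(self):
        codes = lbp_encode(np.full((8, 8), 0.5), P=8, R=1)
        np.testing.assert_array_equal(codes, 255)

    def test_dominant_center_gives_zero(self):
        img = np.ones((5, 5))
        img[2, 2] = 9.0
        assert lbp_encode(img, P=8, R=1)[2, 2] == 0

    def test_explicit_pattern_matches_enumeration(self):
        img = np.array([[5.0, 1.0, 1.0], [1.0, 3.0, 1.0], [1.0, 1.0, 9.0]])
        img = np.pad(img, 1, mode="edge")  # 5x5 so the radius fits
        codes = lbp_encode(img, P=8, R=1)
        ref = lbp_reference(img, P=8, R=1)
        assert codes[2, 2] == ref[2, 2]
        np.testing.assert_array_equal(codes, ref)

    def test_vectorized_equals_bitwise_enumeration_on_random_images(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            img = rng.random((16, 16))
            np.testing.assert_array_equal(lbp_encode(img, P=8, R=1),
                                          lbp_reference(img, P=8, R=1))

    def test_code_range_and_scaling(self):
        rng = np.random.default_rng(13)
        img = rng.random((12, 12))
        codes = lbp_encode(img, P=8, R=1)
        assert codes.min() >= 0 and codes.max() <= 255
        scaled = lbp_encode(img, P=8, R=1, scaled=True)
        np.testing.assert_allclose(scaled, codes / 255.0)

    def test_parameter_guards(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            lbp_encode(img, P=25)
        with pytest.raises(ValueError):
            lbp_encode(img, P=3)
        with pytest.raises(ValueError):
            lbp_encode(np.zeros((3, 3)), P=8, R=1)


class TestGabor:
    def test_origin_value_is_one_at_zero_phase(self):
        cfg = GaborBankConfig()
        for lam in cfg.wavelengths:
            for theta in cfg.orientations:
                k = gabor_kernel(cfg, lam, theta)
                assert k[cfg.kernel_size // 2, cfg.kernel_size // 2] == pytest.approx(1.0)

    def test_even_symmetry(self):
        cfg = GaborBankConfig()
        k = gabor_kernel(cfg, 8.0, np.pi / 3)
        np.testing.assert_allclose(k, k[::-1, ::-1], atol=1e-12)

    def test_closed_form_at_half_wavelength(self):
        cfg = GaborBankConfig()
        lam = 8.0
        k = gabor_kernel(cfg, lam, 0.0)
        half = cfg.kernel_size // 2
        sigma = cfg.sigma(lam)
        expected = -np.exp(-lam ** 2 / (8.0 * sigma ** 2))
        assert k[half, half + int(lam // 2)] == pytest.approx(expected, rel=1e-12)

    def test_zero_image_zero_responses(self):
        out = gabor_bank_responses(np.zeros((16, 16)), GaborBankConfig())
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_image_times_kernel_sum(self):
        cfg = GaborBankConfig()
        c = 0.42
        out = gabor_bank_responses(np.full((20, 20), c), cfg)
        i = 0
        for lam in cfg.wavelengths:
            for theta in cfg.orientations:
                ksum = gabor_kernel(cfg, lam, theta).sum()
                np.testing.assert_allclose(out[10, 10, i], c * ksum, rtol=1e-10)
                i += 1

    def test_linearity(self):
        cfg = GaborBankConfig()
        rng = np.random.default_rng(14)
        x, y = rng.random((2, 16, 16))
        lhs = gabor_bank_responses(1.7 * x - 0.4 * y, cfg)
        rhs = 1.7 * gabor_bank_responses(x, cfg) - 0.4 * gabor_bank_responses(y, cfg)
        np.testing.assert_allclose(lhs, rhs, atol=1e-5)

    def test_channel_count_and_config_guards(self):
        cfg = GaborBankConfig()
        assert cfg.n_channels == 8
        out = gabor_bank_responses(np.zeros((16, 16)), cfg)
        assert out.shape == (16, 16, 8)
        with pytest.raises(ValueError):
            GaborBankConfig(kernel_size=14)
        with pytest.raises(ValueError):
            GaborBankConfig(wavelengths=(0.0, 4.0))


class TestPriorStack:
    def test_default_channel_count_is_ten(self):
        stack = build_prior_stack(np.random.default_rng(15).random((16, 16)))
        assert stack.n_channels == 2 + 2 * 4 == 10
        assert stack.stacked.shape == (16, 16, 10)

    def test_channel_zero_is_edge_map(self):
        img = np.random.default_rng(16).random((16, 16))
        stack = build_prior_stack(img)
        np.testing.assert_array_equal(stack.stacked[:, :, 0], laplacian_edge(img))
        np.testing.assert_array_equal(stack.stacked[:, :, 1],
                                      lbp_encode(img, scaled=True))

    def test_deterministic_bit_identical(self):
        img = np.random.default_rng(17).random((16, 16))
        a = build_prior_stack(img).stacked
        b = build_prior_stack(img).stacked
        assert np.array_equal(a, b)


class TestCompression:
    def test_zero_weights_give_zero(self):
        comp = PriorCompressor(10, 16, rng=np.random.default_rng(0))
        comp.conv.weight.data = np.zeros_like(comp.conv.weight.data)
        comp.conv.bias.data = np.zeros_like(comp.conv.bias.data)
        out = compress_priors(np.random.default_rng(1).random((8, 8, 10)), comp)
        np.testing.assert_array_equal(out, 0.0)  # GELU(0) = 0

    def test_identity_kernel_passes_large_positive_values(self):
        comp = PriorCompressor(1, 1, rng=np.random.default_rng(0))
        comp.conv.weight.data = np.zeros_like(comp.conv.weight.data)
        comp.conv.weight.data[0, 0, 1, 1] = 1.0
        comp.conv.bias.data = np.zeros_like(comp.conv.bias.data)
        img = np.random.default_rng(2).uniform(4.0, 8.0, (6, 6, 1))
        out = compress_priors(img, comp)
        np.testing.assert_allclose(out[0, 0], img[:, :, 0], atol=1e-3)

    def test_output_channels_and_mismatch_guard(self):
        comp = PriorCompressor(10, 16, rng=np.random.default_rng(0))
        out = compress_priors(np.zeros((8, 8, 10)), comp)
        assert out.shape == (1, 16, 8, 8)
        with pytest.raises(ValueError):
            compress_priors(np.zeros((8, 8, 3)), comp)


class TestAttentionFusion:
    @staticmethod
    def _identity_fusion(c):
        fusion = AttentionFusion(c, c, rng=np.random.default_rng(0))
        fusion.projection.weight.data = np.eye(c).reshape(c, c, 1, 1)
        fusion.projection.bias.data = np.zeros(c)
        fusion.w_alpha.weight.data = np.zeros((c, c))
        fusion.w_beta.weight.data = np.zeros((c, c))
        return fusion

    def test_zero_gate_weights_average_streams(self):
        fusion = self._identity_fusion(3)
        rng = np.random.default_rng(3)
        f = rng.random((2, 3, 4, 4))
        t = rng.random((2, 3, 4, 4))
        fused, _ = attention_fuse(f, t, fusion)
        np.testing.assert_allclose(fused, 0.5 * (f + t), atol=1e-12)

    def test_zero_priors_scale_features_only(self):
        fusion = self._identity_fusion(3)
        f = np.random.default_rng(4).random((1, 3, 4, 4))
        fused, _ = attention_fuse(f, np.zeros((1, 3, 4, 4)), fusion)
        np.testing.assert_allclose(fused, 0.5 * f, atol=1e-12)

    def test_hand_computed_two_channel_example(self):
        c = 2
        fusion = self._identity_fusion(c)
        wa = np.array([[0.3, -0.2], [0.1, 0.5]])
        wb = np.array([[-0.4, 0.2], [0.6, -0.1]])
        fusion.w_alpha.weight.data = wa
        fusion.w_beta.weight.data = wb
        rng = np.random.default_rng(5)
        f = rng.random((1, c, 2, 2))
        t = rng.random((1, c, 2, 2))
        fused, _ = attention_fuse(f, t, fusion)
        # scalar arithmetic oracle mirroring the gate formulas
        gap_t = t.mean(axis=(2, 3))[0]
        gap_f = f.mean(axis=(2, 3))[0]
        alpha = 1 / (1 + np.exp(-(gap_t @ wa)))
        beta = 1 / (1 + np.exp(-(gap_f @ wb)))
        expected = alpha[None, :, None, None] * f + beta[None, :, None, None] * t
        np.testing.assert_allclose(fused, expected, atol=1e-12)

    def test_spatial_resize_and_gate_range(self):
        fusion = AttentionFusion(5, 7, rng=np.random.default_rng(6))
        f = np.random.default_rng(7).random((2, 7, 4, 4))
        t = np.random.default_rng(8).random((2, 5, 16, 16))
        fused, tproj = attention_fuse(f, t, fusion)
        assert fused.shape == f.shape
        assert tproj.shape == f.shape


class TestPyramidPool:
    def test_constant_input_maps_to_three_c(self):
        out = pyramid_pool(np.full((1, 2, 8, 8), 0.25))
        np.testing.assert_allclose(out, 0.75, atol=1e-12)

    def test_output_shape_matches_input(self):
        x = np.random.default_rng(9).random((2, 3, 12, 8))
        assert pyramid_pool(x).shape == x.shape

    def test_four_by_four_hand_example(self):
        x = np.arange(16, dtype=float).reshape(4, 4)
        out = pyramid_pool(x)
        expected = np.full((4, 4), x.mean())
        for s in (2, 4):
            blocks = x.reshape(s, 4 // s, s, 4 // s).mean(axis=(1, 3))
            expected += np.kron(blocks, np.ones((4 // s, 4 // s)))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_global_mean_preserved_times_three(self):
        rng = np.random.default_rng(10)
        for size in (4, 8, 16):
            x = rng.random((1, 2, size, size))
            assert pyramid_pool(x).mean() == pytest.approx(3 * x.mean(), abs=1e-6)

    def test_small_input_rejected(self):
        with pytest.raises(ValueError):
            pyramid_pool(np.zeros((1, 1, 3, 8)))


class TestMMD:
    def test_identical_multisets_give_zero(self):
        rng = np.random.default_rng(11)
        a = rng.random((10, 3))
        assert mmd_loss(a, a.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_random_samples(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            a = rng.normal(size=(8, 4))
            b = rng.normal(loc=rng.normal(), size=(12, 4))
            assert mmd_loss(a, b) >= 0.0

    def test_singleton_linear_kernel_closed_form(self):
        x = np.array([[1.0, 2.0, -1.0]])
        y = np.array([[0.5, 0.0, 1.5]])
        out = mmd_loss(x, y, MMDConfig(kernel="linear"))
        assert out == pytest.approx(np.sum((x - y) ** 2), rel=1e-12)

    def test_kernel_trick_matches_explicit_double_sum(self):
        rng = np.random.default_rng(13)
        for n, m in [(5, 7), (20, 20), (1, 9)]:
            a = rng.normal(size=(n, 3))
            b = rng.normal(loc=0.5, size=(m, 3))
            h = 1.3
            fast = mmd_loss(a, b, MMDConfig(bandwidth=h))
            assert fast == pytest.approx(mmd_double_sum(a, b, h), abs=1e-8)

    def test_dimension_mismatch_and_degenerate_bandwidth(self):
        with pytest.raises(ValueError):
            mmd_loss(np.zeros((3, 2)), np.zeros((3, 4)))
        with pytest.warns(UserWarning):
            out = mmd_loss(np.ones((4, 2)), np.ones((4, 2)))
        assert out == pytest.approx(0.0, abs=1e-12)

    def test_gradient_flows_through_rbf_estimator(self):
        rng = np.random.default_rng(14)
        a = Tensor(rng.normal(size=(6, 2)), requires_grad=True)
        b = Tensor(rng.normal(loc=1.0, size=(6, 2)))
        out = mmd_loss(a, b, MMDConfig(bandwidth=1.0))
        out.backward()
        assert np.all(np.isfinite(a.grad)) and np.any(a.grad != 0)
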