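import numpy as np
import pytest

from renalseg.network import (
    DualAttention,
    RDABlock,
    RDAUnet,
    RDAUnetConfig,
    build_rda_unet,
    build_unet_baseline,
    load_checkpoint,
    save_checkpoint,
)
from renalseg.training import dice_loss_grad


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def dual_attention_brute_force(f, wq, bq, wp, bp):
    """Scalar-by-scalar evaluation of Q(F)*F + P(F)*F on one (C,H,W) map.

    Q at (r,c) = sigmoid(sum_k wq[k]*F[k,r,c] + bq); P for channel o =
    sigmoid(sum_k wp[o,k]*mean(F[k]) + bp[o]).
    """
    C, H, W = f.shape
    out = np.zeros_like(f)
    gap = [f[k].mean() for k in range(C)]
    for o in range(C):
        p = sigmoid(sum(wp[o, k] * gap[k] for k in range(C)) + bp[o])
        for r in range(H):
            for c in range(W):
                q = sigmoid(sum(wq[k] * f[k, r, c] for k in range(C)) + bq)
                out[o, r, c] = q * f[o, r, c] + p * f[o, r, c]
    return out


class TestDualAttention:
    def test_zero_weights_identity(self, rng):
        att = DualAttention(3, rng, dtype=np.float64)
        for p in att.parameters():
            p.data[...] = 0.0
        f = rng.standard_normal((2, 3, 5, 5))
        out = att.forward(f)
        np.testing.assert_allclose(out, f, atol=1e-12)  # 0.5F + 0.5F

    def test_output_shape_equals_input_shape(self, rng):
        att = DualAttention(4, rng)
        f = rng.standard_normal((3, 4, 6, 6)).astype(np.float32)
        assert att.forward(f).shape == f.shape

    @pytest.mark.parametrize("c,h", [(1, 2), (2, 3), (2, 4)])
    def test_matches_scalar_brute_force(self, rng, c, h):
        att = DualAttention(c, rng, dtype=np.float64)
        # hand-set 1x1 weights
        wq = rng.standard_normal(c)
        bq = float(rng.standard_normal())
        wp = rng.standard_normal((c, c))
        bp = rng.standard_normal(c)
        att.spatial_conv.weight.data[...] = wq.reshape(1, c, 1, 1)
        att.spatial_conv.bias.data[...] = bq
        att.channel_conv.weight.data[...] = wp.reshape(c, c, 1, 1)
        att.channel_conv.bias.data[...] = bp
        f = rng.standard_normal((2, c, h, h))
        out = att.forward(f)
        for n in range(2):
            expected = dual_attention_brute_force(f[n], wq, bq, wp, bp)
            np.testing.assert_allclose(out[n], expected, atol=1e-10)

    def test_attention_maps_in_open_unit_interval(self, rng):
        att = DualAttention(3, rng, dtype=np.float64)
        f = rng.standard_normal((2, 3, 8, 8)) * 10
        q, p = att.attention_maps(f)
        assert q.shape == (2, 1, 8, 8) and p.shape == (2, 3, 1, 1)
        for arr in (q, p):
            assert np.all(arr > 0) and np.all(arr < 1)


class TestRDABlock:
    def test_output_nonnegative(self, rng):
        block = RDABlock(2, 4, use_bn=True, rng=rng, dtype=np.float64)
        out = block.forward(rng.standard_normal((2, 2, 8, 8)))
        assert np.all(out >= 0)

    def test_zero_input_zero_output(self, rng):
        block = RDABlock(3, 3, use_bn=False, rng=rng, dtype=np.float64)
        out = block.forward(np.zeros((1, 3, 6, 6)))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_no_projection_when_channels_match(self, rng):
        assert RDABlock(4, 4, True, rng).project is None
        assert RDABlock(2, 4, True, rng).project is not None

    def test_residual_path_passes_input_through(self, rng):
        """With the conv branch forced to zero the block is ReLU(att(0) + X)
        = ReLU(X), since the attention of a zero map is zero."""
        block = RDABlock(3, 3, use_bn=False, rng=rng, dtype=np.float64)
        block.conv1.conv.weight.data[...] = 0.0
        block.conv1.conv.bias.data[...] = 0.0
        x = rng.standard_normal((2, 3, 6, 6))
        out = block.forward(x)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-12)


def manual_forward_depth1(model, x):
    """Step-by-step naive recomputation of a depth-1, no-BN RDA-UNet."""

    def conv_same(x, w, b):
        n, ci, h, wd = x.shape
        co, _, k, _ = w.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        out = np.zeros((n, co, h, wd))
        for nn in range(n):
            for o in range(co):
                for r in range(h):
                    for c in range(wd):
                        acc = b[o]
                        for i in range(ci):
                            for dr in range(k):
                                for dc in range(k):
                                    acc += w[o, i, dr, dc] * xp[nn, i, r + dr, c + dc]
                        out[nn, o, r, c] = acc
        return out

    def block(x, blk):
        f = np.maximum(conv_same(x, blk.conv1.conv.weight.data,
                                 blk.conv1.conv.bias.data), 0.0)
        f = np.maximum(conv_same(f, blk.conv2.conv.weight.data,
                                 blk.conv2.conv.bias.data), 0.0)
        att = blk.attention
        q = sigmoid(conv_same(f, att.spatial_conv.weight.data,
                              att.spatial_conv.bias.data))
        gap = f.mean(axis=(2, 3), keepdims=True)
        p = sigmoid(conv_same(gap, att.channel_conv.weight.data,
                              att.channel_conv.bias.data))
        y = q * f + p * f
        skip = conv_same(x, blk.project.weight.data, blk.project.bias.data) \
            if blk.project is not None else x
        return np.maximum(y + skip, 0.0)

    h0 = block(x, model.enc_blocks[0])
    # 2x2 max pool
    n, c, hh, ww = h0.shape
    pooled = h0.reshape(n, c, hh // 2, 2, ww // 2, 2).max(axis=(3, 5))
    b = np.maximum(conv_same(pooled, model.bottleneck1.conv.weight.data,
                             model.bottleneck1.conv.bias.data), 0.0)
    b = np.maximum(conv_same(b, model.bottleneck2.conv.weight.data,
                             model.bottleneck2.conv.bias.data), 0.0)
    # transposed conv 2x2 stride 2
    up = model.upsamples[0]
    n, ci, hh, ww = b.shape
    co = up.out_channels
    y = np.zeros((n, co, 2 * hh, 2 * ww))
    for nn in range(n):
        for o in range(co):
            for r in range(hh):
                for c in range(ww):
                    for i in range(2):
                        for j in range(2):
                            for k in range(ci):
                                y[nn, o, 2 * r + i, 2 * c + j] += \
                                    b[nn, k, r, c] * up.weight.data[k, o, i, j]
            y[nn, o] += up.bias.data[o]
    cat = np.concatenate([h0, y], axis=1)
    d = block(cat, model.dec_blocks[0])
    logits = conv_same(d, model.classifier.weight.data,
                       model.classifier.bias.data)
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


class TestRDAUnet:
    def test_output_shape_and_softmax(self, rng):
        cfg = RDAUnetConfig(depth=2, base_channels=4)
        model = RDAUnet(cfg, seed=0)
        x = rng.standard_normal((2, 1, 32, 32)).astype(np.float32)
        probs = model.forward(x)
        assert probs.shape == (2, 2, 32, 32)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("side", [16, 32, 48])
    def test_shape_preserved_for_any_valid_side(self, rng, side):
        model = RDAUnet(RDAUnetConfig(depth=2, base_channels=2), seed=0)
        probs = model.forward(rng.standard_normal((1, 1, side, side)).astype(np.float32))
        assert probs.shape == (1, 2, side, side)

    def test_invalid_input_size_rejected(self, rng):
        model = RDAUnet(RDAUnetConfig(depth=3, base_channels=2), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 1, 20, 20), dtype=np.float32))

    def test_manual_forward_oracle_depth1(self, rng):
        cfg = RDAUnetConfig(depth=1, base_channels=1, use_batch_norm=False)
        model = RDAUnet(cfg, seed=4, dtype=np.float64)
        x = rng.standard_normal((1, 1, 4, 4))
        np.testing.assert_allclose(model.forward(x), manual_forward_depth1(model, x),
                                   atol=1e-10)

    def test_gradient_flow_every_parameter(self, rng):
        model = RDAUnet(RDAUnetConfig(depth=2, base_channels=4), seed=1,
                        dtype=np.float64)
        x = rng.standard_normal((4, 1, 16, 16))
        y = (rng.random((4, 16, 16)) > 0.5).astype(np.int64)
        probs = model.forward(x)
        _, gprobs = dice_loss_grad(probs, y)
        model.zero_grad()
        model.backward(gprobs)
        for name, p in model.named_parameters():
            assert np.abs(p.grad).max() > 0, f"dead gradient in {name}"

    def test_numerical_gradient_check(self, rng):
        model = RDAUnet(RDAUnetConfig(depth=1, base_channels=2), seed=2,
                        dtype=np.float64)
        x = rng.standard_normal((2, 1, 8, 8))
        y = (rng.random((2, 8, 8)) > 0.5).astype(np.int64)
        probs = model.forward(x)
        _, gprobs = dice_loss_grad(probs, y)
        model.zero_grad()
        model.backward(gprobs)
        eps = 1e-6
        for name, p in model.named_parameters():
            flat, gflat = p.data.ravel(), p.grad.ravel()
            for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = dice_loss_grad(model.forward(x), y)
                flat[i] = orig - eps
                lm, _ = dice_loss_grad(model.forward(x), y)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, abs=2e-6), name

    def test_attention_entries_in_unit_interval(self, rng):
        model = RDAUnet(RDAUnetConfig(depth=2, base_channels=4), seed=0)
        model.eval()
        model.forward(rng.standard_normal((1, 1, 32, 32)).astype(np.float32))
        x = rng.standard_normal((1, 1, 32, 32)).astype(np.float32)
        h = model.enc_blocks[0].conv2.forward(
            model.enc_blocks[0].conv1.forward(x))
        q, p = model.enc_blocks[0].attention.attention_maps(h)
        assert np.all((q > 0) & (q < 1)) and np.all((p > 0) & (p < 1))


class TestBaselines:
    def test_bn_adds_parameters(self):
        cfg = RDAUnetConfig(depth=2, base_channels=4)
        plain = build_unet_baseline(cfg, with_bn=False)
        bn = build_unet_baseline(cfg, with_bn=True)
        assert plain.num_parameters() < bn.num_parameters()

    def test_rda_has_more_parameters_than_unet_bn(self):
        cfg = RDAUnetConfig(depth=2, base_channels=4)
        rda = build_rda_unet(cfg)
        bn = build_unet_baseline(cfg, with_bn=True)
        assert rda.num_parameters() > bn.num_parameters()

    def test_parameter_count_by_module_enumeration(self):
        """Independent count: sum array sizes over an explicit module walk."""
        cfg = RDAUnetConfig(depth=1, base_channels=2)
        model = build_unet_baseline(cfg, with_bn=False)
        expected = 0
        for blk in model.enc_blocks + model.dec_blocks:
            for cv in (blk.conv1.conv, blk.conv2.conv):
                expected += cv.weight.data.size + cv.bias.data.size
        for cv in (model.bottleneck1.conv, model.bottleneck2.conv,
                   model.classifier):
            expected += cv.weight.data.size + cv.bias.data.size
        for up in model.upsamples:
            expected += up.weight.data.size + up.bias.data.size
        assert model.num_parameters() == expected

    def test_baseline_output_contract(self, rng):
        model = build_unet_baseline(RDAUnetConfig(depth=2, base_channels=2),
                                    with_bn=False)
        probs = model.forward(rng.standard_normal((1, 1, 16, 16)).astype(np.float32))
        assert probs.shape == (1, 2, 16, 16)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestCheckpoint:
    def test_roundtrip_predictions_identical(self, tmp_path, rng):
        model = build_rda_unet(RDAUnetConfig(depth=2, base_channels=3), seed=5)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path)
        assert restored.config == model.config
        img = rng.random((16, 16))
        np.testing.assert_array_equal(model.predict_mask(img),
                                      restored.predict_mask(img))

    def test_shape_mismatch_error_names_shapes(self, rng):
        a = build_rda_unet(RDAUnetConfig(depth=1, base_channels=2))
        b = build_rda_unet(RDAUnetConfig(depth=1, base_channels=4))
        with pytest.raises(ValueError, match=r"\("):
            a.load_state_dict(b.state_dict())
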