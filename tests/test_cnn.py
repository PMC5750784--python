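"""Tests of the convolutional identifier: layer oracles, gradients, training."""

import copy

import numpy as np
import pytest

import gaitid as g
from gaitid.cnn import Conv2D, Dense, Flatten, Pool2D, ReLULayer


# ---------------------------------------------------------------------------
# Brute-force oracles, independent of the vectorized implementations
# ---------------------------------------------------------------------------

def conv_loops(x, w, bias, stride, padding):
    B, C, H, W = x.shape
    K, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    OH = (H + 2 * padding - kh) // stride + 1
    OW = (W + 2 * padding - kw) // stride + 1
    out = np.zeros((B, K, OH, OW))
    for b in range(B):
        for k in range(K):
            for i in range(OH):
                for j in range(OW):
                    acc = 0.0
                    for c in range(C):
                        for di in range(kh):
                            for dj in range(kw):
                                acc += (w[k, c, di, dj]
                                        * xp[b, c, i * stride + di,
                                             j * stride + dj])
                    out[b, k, i, j] = acc + (bias[k] if bias is not None else 0.0)
    return out


def pool_loops(x, window, stride, mode):
    B, C, H, W = x.shape
    hp, wp = window
    OH = (H - hp) // stride + 1
    OW = (W - wp) // stride + 1
    out = np.zeros((B, C, OH, OW))
    op = np.max if mode == "max" else np.min
    for b in range(B):
        for c in range(C):
            for i in range(OH):
                for j in range(OW):
                    out[b, c, i, j] = op(x[b, c, i * stride:i * stride + hp,
                                           j * stride:j * stride + wp])
    return out


class TestForwardOracles:
    def test_conv_known_example(self):
        x = np.arange(1.0, 10.0).reshape(1, 1, 3, 3)
        w = np.ones((1, 1, 2, 2))
        out = g.conv_forward(x, w, stride=1, padding=0)
        np.testing.assert_allclose(out[0, 0], [[12, 16], [24, 28]])

    def test_identity_kernel(self):
        x = np.random.default_rng(0).normal(size=(2, 3, 5, 5))
        w = np.zeros((3, 3, 1, 1))
        for c in range(3):
            w[c, c, 0, 0] = 1.0
        np.testing.assert_allclose(g.conv_forward(x, w), x)

    def test_conv_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(1, 2, 6, 6))
        w = rng.normal(size=(4, 2, 3, 3))
        np.testing.assert_allclose(g.conv_forward(3.0 * x, w),
                                   3.0 * g.conv_forward(x, w), rtol=1e-12)

    def test_conv_matches_loop_oracle_fuzz(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            B, C, K = rng.integers(1, 3), rng.integers(1, 4), rng.integers(1, 4)
            kh, kw = rng.integers(1, 4, size=2)
            stride = int(rng.integers(1, 3))
            padding = int(rng.integers(0, 2))
            H = int(rng.integers(kh, kh + 5))
            W = int(rng.integers(kw, kw + 5))
            x = rng.normal(size=(B, C, H, W))
            w = rng.normal(size=(K, C, kh, kw))
            b = rng.normal(size=K)
            got = g.conv_forward(x, w, b, stride=stride, padding=padding)
            want = conv_loops(x, w, b, stride, padding)
            np.testing.assert_allclose(got, want, atol=1e-6)

    def test_conv_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            g.conv_forward(np.zeros((1, 2, 4, 4)), np.zeros((1, 3, 3, 3)))

    def test_pool_known_example(self):
        x = np.arange(1.0, 17.0).reshape(1, 1, 4, 4)
        out = g.pool_forward(x, (2, 2), 2, "max")
        np.testing.assert_allclose(out[0, 0], [[6, 8], [14, 16]])

    def test_pool_constant_image(self):
        x = np.full((1, 2, 4, 4), 1.5)
        np.testing.assert_allclose(g.pool_forward(x, (2, 2), 2), 1.5)

    def test_min_max_duality(self):
        x = np.random.default_rng(2).normal(size=(2, 3, 6, 6))
        np.testing.assert_array_equal(
            g.pool_forward(x, (2, 2), 2, "min"),
            -g.pool_forward(-x, (2, 2), 2, "max"))

    def test_pool_matches_loop_oracle_fuzz(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            hp, wp = rng.integers(1, 4, size=2)
            stride = int(rng.integers(1, 3))
            H = int(rng.integers(hp, hp + 5))
            W = int(rng.integers(wp, wp + 5))
            x = rng.normal(size=(2, 2, H, W))
            mode = ["max", "min"][int(rng.integers(0, 2))]
            got = g.pool_forward(x, (hp, wp), stride, mode)
            want = pool_loops(x, (hp, wp), stride, mode)
            np.testing.assert_array_equal(got, want)

    def test_pool_window_too_large_rejected(self):
        with pytest.raises(ValueError):
            g.pool_forward(np.zeros((1, 1, 2, 2)), (3, 3), 1)

    def test_relu(self):
        np.testing.assert_array_equal(g.relu_forward(np.array([-1.0, 0.0, 2.0])),
                                      [0.0, 0.0, 2.0])
        x = np.abs(np.random.default_rng(3).normal(size=(4, 4)))
        np.testing.assert_array_equal(g.relu_forward(x), x)
        y = np.random.default_rng(4).normal(size=(4, 4))
        np.testing.assert_array_equal(g.relu_forward(g.relu_forward(y)),
                                      g.relu_forward(y))


# ---------------------------------------------------------------------------
# Gradient checks against central finite differences
# ---------------------------------------------------------------------------

def check_gradients(layer, x, rtol=1e-4, seed=0):
    """Analytic backward pass vs central finite differences on a random
    scalar projection of the layer output."""
    rng = np.random.default_rng(seed)
    out = layer.forward(x, train=True)
    proj = rng.normal(size=out.shape)
    dx = layer.backward(proj)

    eps = 1e-6

    def loss(inp):
        return float(np.sum(layer.forward(inp, train=False) * proj))

    fd = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd[idx] = (loss(xp) - loss(xm)) / (2 * eps)
    np.testing.assert_allclose(dx, fd, rtol=rtol, atol=1e-7)

    for p, grad in zip(layer.params, layer.grads):
        fdp = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + eps
            lp = loss(x)
            p[idx] = orig - eps
            lm = loss(x)
            p[idx] = orig
            fdp[idx] = (lp - lm) / (2 * eps)
        np.testing.assert_allclose(grad, fdp, rtol=rtol, atol=1e-7)


class TestGradients:
    rng = np.random.default_rng(123)

    def test_conv_gradients(self):
        layer = Conv2D(2, 3, 3, 1, np.random.default_rng(0), dtype=np.float64)
        x = self.rng.normal(size=(2, 2, 5, 5))
        check_gradients(layer, x)

    @pytest.mark.parametrize("mode", ["max", "min"])
    def test_pool_gradients(self, mode):
        layer = Pool2D(2, mode)
        # distinct values avoid FD ambiguity at pooling ties
        x = self.rng.permutation(np.arange(2 * 2 * 4 * 4.0)).reshape(2, 2, 4, 4)
        check_gradients(layer, x)

    def test_relu_gradients(self):
        layer = ReLULayer()
        x = self.rng.normal(size=(3, 2, 4, 4))
        x[np.abs(x) < 1e-3] = 0.5  # keep FD away from the kink
        check_gradients(layer, x)

    def test_dense_gradients(self):
        layer = Dense(12, 5, np.random.default_rng(1), dtype=np.float64)
        x = self.rng.normal(size=(4, 12))
        check_gradients(layer, x)

    def test_flatten_roundtrip(self):
        layer = Flatten()
        x = self.rng.normal(size=(2, 3, 4, 4))
        out = layer.forward(x, train=True)
        np.testing.assert_array_equal(layer.backward(out), x)


# ---------------------------------------------------------------------------
# Model construction and training
# ---------------------------------------------------------------------------

class TestModel:
    def small_cfg(self, **kw):
        defaults = dict(num_classes=3, image_size=16, epochs=3, batch_size=8,
                        seed=5)
        defaults.update(kw)
        return g.DcnnConfig(**defaults)

    def test_forward_posterior_sums_to_one(self):
        model = g.build_model(self.small_cfg())
        x = np.random.default_rng(0).normal(size=(4, 3, 16, 16))
        _, post = model.predict_scores(x)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)

    def test_equal_seeds_equal_parameters(self):
        a = g.build_model(self.small_cfg())
        b = g.build_model(self.small_cfg())
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_early_fusion_channel_width(self):
        model = g.build_model(self.small_cfg(input_channels=30))
        assert model.layers[0].w.shape[1] == 30
        x = np.random.default_rng(0).normal(size=(2, 30, 16, 16))
        _, post = model.predict_scores(x)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_image_size_rejected(self):
        with pytest.raises(ValueError):
            self.small_cfg(image_size=30)

    def test_zero_learning_rate_freezes_parameters(self):
        cfg = self.small_cfg(learning_rate=0.0)
        model = g.build_model(cfg)
        before = [p.copy() for p, _ in model.parameters()]
        rng = np.random.default_rng(1)
        x = rng.normal(size=(16, 3, 16, 16)).astype(np.float32)
        y = rng.integers(1, 4, size=16)
        g.train_model(model, x, y, cfg)
        for b, (p, _) in zip(before, model.parameters()):
            np.testing.assert_array_equal(b, p)
        losses = [h["loss"] for h in model.history]
        assert max(losses) - min(losses) < 1e-6

    def test_separable_images_reach_full_training_accuracy(self):
        # two subjects whose images differ grossly (bright top vs bottom
        # half): a linear probe already separates them, and the model must
        # reach 100% training accuracy within the fixed epoch budget
        cfg = self.small_cfg(num_classes=2, epochs=19, batch_size=8, seed=2)
        rng = np.random.default_rng(0)
        x = 0.05 * rng.normal(size=(40, 3, 16, 16)).astype(np.float32)
        y = np.array([1, 2] * 20)
        x[y == 1, :, :8, :] += 1.0
        x[y == 2, :, 8:, :] += 1.0
        model = g.build_model(cfg)
        g.train_model(model, x, y, cfg)
        assert model.history[-1]["train_acc"] == 100.0

    def test_first_epoch_reduces_loss(self):
        cfg = self.small_cfg(num_classes=2, epochs=2, seed=3)
        rng = np.random.default_rng(4)
        x = 0.05 * rng.normal(size=(24, 3, 16, 16)).astype(np.float32)
        y = np.array([1, 2] * 12)
        x[y == 1, :, :8, :] += 1.0
        x[y == 2, :, 8:, :] += 1.0
        model = g.build_model(cfg)
        z = model.logits(x).astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        log_p = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        initial_loss = -log_p[np.arange(24), y - 1].mean()
        g.train_model(model, x, y, cfg)
        assert model.history[0]["loss"] <= initial_loss

    def test_training_is_deterministic(self):
        cfg = self.small_cfg(epochs=2)
        rng = np.random.default_rng(5)
        x = rng.normal(size=(16, 3, 16, 16)).astype(np.float32)
        y = rng.integers(1, 4, size=16)
        runs = []
        for _ in range(2):
            model = g.build_model(cfg)
            g.train_model(model, x, y, cfg)
            runs.append(copy.deepcopy([p for p, _ in model.parameters()]))
        for pa, pb in zip(*runs):
            np.testing.assert_array_equal(pa, pb)

    def test_label_out_of_range_rejected(self):
        cfg = self.small_cfg()
        model = g.build_model(cfg)
        x = np.zeros((4, 3, 16, 16), dtype=np.float32)
        with pytest.raises(ValueError, match="labels"):
            g.train_model(model, x, np.array([1, 2, 3, 4]), cfg)

    def test_predict_scores_properties(self):
        model = g.build_model(self.small_cfg())
        x = np.random.default_rng(6).normal(size=(3, 3, 16, 16))
        log_p, post = model.predict_scores(x)
        np.testing.assert_allclose(np.exp(log_p).sum(axis=1), 1.0, atol=1e-6)
        log_p2, _ = model.predict_scores(x.copy())
        np.testing.assert_array_equal(log_p, log_p2)
        np.testing.assert_array_equal(np.argmax(log_p, axis=1),
                                      np.argmax(post, axis=1))
        with pytest.raises(ValueError, match="channel"):
            model.predict_scores(np.zeros((2, 5, 16, 16)))

    def test_save_load_roundtrip(self, tmp_path):
        cfg = self.small_cfg(epochs=1)
        model = g.build_model(cfg, source_id=(1, "acc"))
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 3, 16, 16)).astype(np.float32)
        y = rng.integers(1, 4, size=8)
        g.train_model(model, x, y, cfg)
        g.save_model(model, tmp_path / "m")
        loaded = g.load_model(tmp_path / "m")
        np.testing.assert_array_equal(model.predict(x), loaded.predict(x))
        assert loaded.source_id == (1, "acc")
        assert loaded.history == model.history
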