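"""Numeric engine: every layer is checked against an independent oracle
(scipy.ndimage for convolution, finite differences for all gradients)."""

import numpy as np
import pytest
from scipy import ndimage

from comproseg.nn import (
    Adam,
    Conv,
    InstanceNorm,
    MaxPool2,
    Param,
    ReLU,
    ShapeError,
    UpConv2,
    softmax,
    softmax_backward,
)

RNG = np.random.default_rng(0)


def numeric_grad(f, x, eps=1e-3):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g


def layer_loss(layer, x, w):
    """Scalar probe loss sum(forward * w) for gradient checking."""
    return float((layer.forward(x.astype(np.float32)) * w).sum())


def check_input_grad(layer, x, rtol=2e-2):
    w = RNG.normal(size=layer.forward(x.astype(np.float32)).shape)
    y = layer.forward(x.astype(np.float32))
    dx = layer.backward(w.astype(np.float32))
    num = numeric_grad(lambda a: layer_loss(layer, a, w), x.astype(np.float64))
    assert np.allclose(dx, num, rtol=rtol, atol=2e-3), (
        f"max abs err {np.abs(dx - num).max()}")


class TestConv:
    @pytest.mark.parametrize("rank,kernel", [(2, 3), (3, 3), (2, 1), (3, 1)])
    def test_forward_matches_scipy_correlate(self, rank, kernel):
        in_ch, out_ch = 2, 3
        conv = Conv(in_ch, out_ch, kernel, rank, np.random.default_rng(1))
        sp = (6, 5) if rank == 2 else (5, 4, 6)
        x = np.random.default_rng(2).normal(size=(2, in_ch, *sp)).astype(np.float32)
        y = conv.forward(x)
        # oracle: sum over input channels of zero-padded correlation
        ref = np.zeros_like(y)
        for n in range(x.shape[0]):
            for f in range(out_ch):
                acc = np.zeros(sp)
                for c in range(in_ch):
                    k = conv.w.value[f, c].reshape((kernel,) * rank)
                    acc += ndimage.correlate(x[n, c].astype(np.float64), k,
                                             mode="constant", cval=0.0)
                ref[n, f] = acc + conv.b.value[f]
        assert np.allclose(y, ref, atol=1e-4)

    def test_wrong_channel_count_rejected(self):
        conv = Conv(2, 3, 3, 2, np.random.default_rng(0))
        with pytest.raises(ShapeError):
            conv.forward(np.zeros((1, 5, 4, 4), dtype=np.float32))

    @pytest.mark.parametrize("rank,kernel", [(2, 3), (3, 3), (2, 1)])
    def test_input_gradient(self, rank, kernel):
        conv = Conv(2, 2, kernel, rank, np.random.default_rng(3))
        sp = (4, 4) if rank == 2 else (4, 4, 4)
        x = np.random.default_rng(4).normal(size=(1, 2, *sp))
        check_input_grad(conv, x)

    def test_weight_gradient(self):
        conv = Conv(2, 2, 3, 2, np.random.default_rng(5))
        x = np.random.default_rng(6).normal(size=(1, 2, 5, 5)).astype(np.float32)
        w = RNG.normal(size=(1, 2, 5, 5))
        conv.forward(x)
        conv.w.grad[...] = 0
        conv.b.grad[...] = 0
        conv.backward(w.astype(np.float32))
        got_w, got_b = conv.w.grad.copy(), conv.b.grad.copy()

        def loss_of_weights(wv):
            c = Conv(2, 2, 3, 2, np.random.default_rng(5))
            c.w.value = wv.astype(np.float32)
            c.b.value = conv.b.value
            return float((c.forward(x) * w).sum())

        num = numeric_grad(loss_of_weights, conv.w.value.astype(np.float64))
        assert np.allclose(got_w, num, rtol=2e-2, atol=2e-3)
        assert np.allclose(got_b, w.sum(axis=(0, 2, 3)), rtol=1e-4)


class TestInstanceNorm:
    def test_normalizes_per_sample_channel(self):
        layer = InstanceNorm(3)
        x = np.random.default_rng(7).normal(5, 3, size=(2, 3, 8, 8)).astype(np.float32)
        y = layer.forward(x)
        assert np.allclose(y.mean(axis=(2, 3)), 0, atol=1e-5)
        assert np.allclose(y.std(axis=(2, 3)), 1, atol=1e-3)

    def test_affine_applied(self):
        layer = InstanceNorm(2)
        layer.g.value[:] = [2.0, 0.5]
        layer.b.value[:] = [1.0, -1.0]
        x = np.random.default_rng(8).normal(size=(1, 2, 6, 6)).astype(np.float32)
        y = layer.forward(x)
        assert np.allclose(y.mean(axis=(2, 3)), [[1.0, -1.0]], atol=1e-5)
        assert np.allclose(y.std(axis=(2, 3)), [[2.0, 0.5]], atol=1e-3)

    def test_input_gradient(self):
        layer = InstanceNorm(2)
        x = np.random.default_rng(9).normal(size=(1, 2, 4, 4))
        check_input_grad(layer, x)


class TestMaxPool2:
    def test_forward_matches_blockwise_max(self):
        pool = MaxPool2()
        x = np.random.default_rng(10).normal(size=(2, 3, 6, 4, 8)).astype(np.float32)
        y = pool.forward(x)
        assert y.shape == (2, 3, 3, 2, 4)
        for i, j, k in ((0, 0, 0), (2, 1, 3), (1, 0, 2)):
            block = x[1, 2, 2 * i:2 * i + 2, 2 * j:2 * j + 2, 2 * k:2 * k + 2]
            assert y[1, 2, i, j, k] == block.max()

    def test_odd_extent_rejected_names_axis(self):
        pool = MaxPool2()
        with pytest.raises(ShapeError, match="axis 1"):
            pool.forward(np.zeros((1, 1, 4, 5, 4), dtype=np.float32))

    def test_backward_routes_to_argmax(self):
        pool = MaxPool2()
        x = np.random.default_rng(11).normal(size=(1, 1, 4, 4))
        check_input_grad(pool, x)


class TestUpConv2:
    @pytest.mark.parametrize("rank", [2, 3])
    def test_doubles_every_extent(self, rank):
        up = UpConv2(3, 2, rank, np.random.default_rng(12))
        sp = (3, 4) if rank == 2 else (2, 3, 4)
        y = up.forward(np.random.default_rng(13).normal(size=(2, 3, *sp)).astype(np.float32))
        assert y.shape == (2, 2) + tuple(2 * s for s in sp)

    def test_single_voxel_broadcast(self):
        # a 1x1 input places w[c,f,a,b]*x in the corresponding 2x2 quadrant
        up = UpConv2(1, 1, 2, np.random.default_rng(14))
        x = np.full((1, 1, 1, 1), 2.0, dtype=np.float32)
        y = up.forward(x)
        assert np.allclose(y[0, 0], 2.0 * up.w.value[0, 0] + up.b.value[0])

    @pytest.mark.parametrize("rank", [2, 3])
    def test_input_gradient(self, rank):
        up = UpConv2(2, 2, rank, np.random.default_rng(15))
        sp = (3, 3) if rank == 2 else (2, 2, 3)
        x = np.random.default_rng(16).normal(size=(1, 2, *sp))
        check_input_grad(up, x)


class TestSoftmax:
    def test_matches_scipy(self):
        from scipy.special import softmax as ref
        x = np.random.default_rng(17).normal(size=(2, 3, 4, 4))
        assert np.allclose(softmax(x, axis=1), ref(x, axis=1))

    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(18)
        s = rng.normal(size=(1, 3, 2, 2))
        w = rng.normal(size=s.shape)
        p = softmax(s, axis=1)
        ds = softmax_backward(p, w, axis=1)
        num = numeric_grad(lambda a: float((softmax(a, axis=1) * w).sum()), s,
                           eps=1e-5)
        assert np.allclose(ds, num, atol=1e-5)


class TestReLUAndAdam:
    def test_relu_gates_gradient(self):
        r = ReLU()
        x = np.array([[-1.0, 2.0, 0.0, 3.0]], dtype=np.float32)
        y = r.forward(x)
        assert (y == [[0, 2, 0, 3]]).all()
        assert (r.backward(np.ones_like(x)) == [[0, 1, 0, 1]]).all()

    def test_adam_first_step_is_lr_times_sign(self):
        p = Param(np.array([1.0, -2.0]))
        opt = Adam([p], lr=0.1)
        p.grad[:] = [0.5, -3.0]
        opt.step()
        # bias-corrected first step = lr * g / (|g| + eps) ~ lr * sign(g)
        assert np.allclose(p.value, [1.0 - 0.1, -2.0 + 0.1], atol=1e-6)

    def test_zero_grad(self):
        p = Param(np.ones(3))
        opt = Adam([p])
        p.grad[:] = 5
        opt.zero_grad()
        assert (p.grad == 0).all()
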