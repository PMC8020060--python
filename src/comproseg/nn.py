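"""Minimal layer library for the segmentation networks.

Arrays are (N, C, *spatial) float32 with spatial rank 2 or 3. Convolutions
are im2col + GEMM with explicit backward passes; the column matrix is
rebuilt during backward instead of cached, trading a little compute for
peak memory (whole 3D volumes are processed at batch size 1).

Only what the U-Nets need exists here: odd-kernel "same" convolution,
2x max pooling, 2x transposed-convolution upsampling, ReLU, channel concat,
softmax, and an Adam optimizer.
"""

from __future__ import annotations

import numpy as np


class ShapeError(ValueError):
    pass


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


class Conv:
    """Odd-kernel zero-padded convolution preserving spatial shape.

    Implemented as one GEMM per kernel tap on a contiguous view of the
    zero-padded, flattened input: for valid positions, flattened-index
    arithmetic equals coordinate arithmetic, so no im2col gather is needed.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, spatial_rank: int,
                 rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.rank = kernel, spatial_rank
        k = kernel**spatial_rank
        std = np.sqrt(2.0 / (in_ch * k))  # He init for ReLU nets
        self.w = Param(rng.normal(0.0, std, size=(out_ch, in_ch, k)))
        self.b = Param(np.zeros(out_ch))
        self._xpf = None

    def params(self):
        return [self.w, self.b]

    def _geometry(self, sp: tuple[int, ...]):
        r = self.kernel // 2
        padded = tuple(s + 2 * r for s in sp)
        strides = np.cumprod((1,) + padded[:0:-1])[::-1]  # row-major flat strides
        offsets = [int(np.dot(off, strides))
                   for off in np.ndindex(*([self.kernel] * self.rank))]
        center = offsets[len(offsets) // 2]  # flat index of the (r,..,r) tap
        return r, padded, offsets, center

    def _pad_flat(self, a: np.ndarray, r: int) -> np.ndarray:
        """(N, C, *sp) -> contiguous (C, N*prod(padded sp))."""
        pad = [(0, 0), (0, 0)] + [(r, r)] * self.rank
        ap = np.pad(a, pad)
        return np.ascontiguousarray(np.moveaxis(ap, 1, 0)).reshape(a.shape[1], -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_ch:
            raise ShapeError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        x = np.ascontiguousarray(x, dtype=np.float32)
        n, sp = x.shape[0], x.shape[2:]
        if self.kernel == 1:
            xf = np.moveaxis(x, 1, 0).reshape(self.in_ch, -1)
            self._xpf, self._shape = np.ascontiguousarray(xf), x.shape
            y = self.w.value[:, :, 0] @ self._xpf
            y = y.reshape(self.out_ch, n, *sp)
            y += self.b.value.reshape(-1, *([1] * (self.rank + 1)))
            return np.ascontiguousarray(np.moveaxis(y, 0, 1))
        r, padded, offsets, _ = self._geometry(sp)
        xpf = self._pad_flat(x, r)
        self._xpf, self._shape = xpf, x.shape
        total = xpf.shape[1]
        z = np.zeros((self.out_ch, total), dtype=np.float32)
        for k, o in enumerate(offsets):
            L = total - o
            z[:, :L] += self.w.value[:, :, k] @ xpf[:, o:]
        zg = z.reshape(self.out_ch, n, *padded)
        core = (slice(None), slice(None)) + tuple(slice(0, s) for s in sp)
        y = zg[core] + self.b.value.reshape(-1, *([1] * (self.rank + 1)))
        return np.ascontiguousarray(np.moveaxis(y, 0, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, sp = self._shape[0], self._shape[2:]
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        if self.kernel == 1:
            dym = np.moveaxis(dy, 1, 0).reshape(self.out_ch, -1)
            self.w.grad[:, :, 0] += dym @ self._xpf.T
            self.b.grad += dym.sum(axis=1)
            dx = self.w.value[:, :, 0].T @ dym
            self._xpf = None
            return np.ascontiguousarray(np.moveaxis(dx.reshape(self.in_ch, n, *sp), 0, 1))
        r, padded, offsets, center = self._geometry(sp)
        dypf = self._pad_flat(dy, r)  # zero padding keeps junk terms silent
        xpf = self._xpf
        total = xpf.shape[1]
        self.b.grad += dy.sum(axis=tuple([0] + list(range(2, dy.ndim))))
        dz = np.zeros((self.in_ch, total), dtype=np.float32)
        for k, o in enumerate(offsets):
            # weight gradient: dW_k[f,c] = sum_q dy_pad[f, q] * x_pad[c, q + o - center]
            s = o - center
            if s >= 0:
                self.w.grad[:, :, k] += dypf[:, : total - s] @ xpf[:, s:].T
            else:
                self.w.grad[:, :, k] += dypf[:, -s:] @ xpf[:, : total + s].T
            # input gradient: correlation of dy with the flipped kernel
            kf = len(offsets) - 1 - k
            L = total - o
            dz[:, :L] += self.w.value[:, :, kf].T @ dypf[:, o:]
        dzg = dz.reshape(self.in_ch, n, *padded)
        core = (slice(None), slice(None)) + tuple(slice(0, s) for s in sp)
        self._xpf = None
        return np.ascontiguousarray(np.moveaxis(dzg[core], 0, 1))


class InstanceNorm:
    """Per-sample, per-channel normalization over spatial positions with a
    learned affine (gamma, beta). Keeps activations and logits conditioned
    at batch size 1, where batch statistics are unavailable."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.g = Param(np.ones(channels))
        self.b = Param(np.zeros(channels))
        self.eps = eps

    def params(self):
        return [self.g, self.b]

    def forward(self, x):
        ax = tuple(range(2, x.ndim))
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        shape = (1, -1) + (1,) * (x.ndim - 2)
        return self.g.value.reshape(shape) * self._xhat + self.b.value.reshape(shape)

    def backward(self, dy):
        ax = tuple(range(2, dy.ndim))
        m = np.prod([dy.shape[i] for i in ax])
        shape = (1, -1) + (1,) * (dy.ndim - 2)
        sum_ax = tuple([0] + list(ax))
        self.g.grad += (dy * self._xhat).sum(axis=sum_ax)
        self.b.grad += dy.sum(axis=sum_ax)
        dxhat = dy * self.g.value.reshape(shape)
        dx = (dxhat - dxhat.mean(axis=ax, keepdims=True)
              - self._xhat * (dxhat * self._xhat).mean(axis=ax, keepdims=True)) * self._inv
        self._xhat = None
        return dx.astype(np.float32)


class ReLU:
    def params(self):
        return []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2:
    """2x max pooling with stride 2; every spatial extent must be even."""

    def params(self):
        return []

    def forward(self, x):
        sp = x.shape[2:]
        if any(s % 2 for s in sp):
            ax = next(i for i, s in enumerate(sp) if s % 2)
            raise ShapeError(f"spatial axis {ax} has odd extent {sp[ax]}; cannot pool")
        rank = len(sp)
        shape = list(x.shape[:2])
        for s in sp:
            shape += [s // 2, 2]
        r = x.reshape(shape)
        # bring the window axes (3, 5, [7]) to the back
        win_axes = [3 + 2 * i for i in range(rank)]
        keep_axes = [0, 1] + [2 + 2 * i for i in range(rank)]
        r = r.transpose(keep_axes + win_axes)
        flat = r.reshape(r.shape[: 2 + rank] + (-1,))
        self._arg = flat.argmax(axis=-1)
        self._inshape = x.shape
        return np.take_along_axis(flat, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        rank = len(self._inshape) - 2
        flat = np.zeros(dy.shape + (2**rank,), dtype=np.float32)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        sp = self._inshape[2:]
        r = flat.reshape(dy.shape[: 2 + rank] + (2,) * rank)
        # invert the forward transpose
        inv = [0, 1]
        for i in range(rank):
            inv += [2 + i, 2 + rank + i]
        r = r.transpose(inv)
        return r.reshape(self._inshape)


class UpConv2:
    """Transposed convolution, kernel 2, stride 2 (doubles every extent)."""

    def __init__(self, in_ch: int, out_ch: int, spatial_rank: int, rng: np.random.Generator):
        self.in_ch, self.out_ch, self.rank = in_ch, out_ch, spatial_rank
        k = 2**spatial_rank
        std = np.sqrt(2.0 / in_ch)
        self.w = Param(rng.normal(0.0, std, size=(in_ch, out_ch) + (2,) * spatial_rank))
        self.b = Param(np.zeros(out_ch))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        self._x = x
        if self.rank == 2:
            y = np.einsum("nchw,cfab->nfhawb", x, self.w.value)
        else:
            y = np.einsum("ncdhw,cfabg->nfdahbwg", x, self.w.value)
        n = x.shape[0]
        sp = tuple(2 * s for s in x.shape[2:])
        y = y.reshape(n, self.out_ch, *sp)
        return y + self.b.value.reshape(-1, *([1] * self.rank))

    def backward(self, dy):
        x, n = self._x, self._x.shape[0]
        sp = x.shape[2:]
        if self.rank == 2:
            d = dy.reshape(n, self.out_ch, sp[0], 2, sp[1], 2)
            self.w.grad += np.einsum("nchw,nfhawb->cfab", x, d)
            dx = np.einsum("nfhawb,cfab->nchw", d, self.w.value)
        else:
            d = dy.reshape(n, self.out_ch, sp[0], 2, sp[1], 2, sp[2], 2)
            self.w.grad += np.einsum("ncdhw,nfdahbwg->cfabg", x, d)
            dx = np.einsum("nfdahbwg,cfabg->ncdhw", d, self.w.value)
        self.b.grad += dy.sum(axis=tuple([0] + list(range(2, dy.ndim))))
        self._x = None
        return np.ascontiguousarray(dx)


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax over the class axis."""
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = 1) -> np.ndarray:
    """Gradient wrt scores given gradient wrt probabilities."""
    dot = (dprobs * probs).sum(axis=axis, keepdims=True)
    return probs * (dprobs - dot)


class Adam:
    """Adam with the usual bias correction; operates on a Param list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, *betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)
            if self.weight_decay:
                # decoupled (AdamW-style) decay: bounds weight and hence
                # logit growth, which keeps the softmax from saturating
                p.value -= self.lr * self.weight_decay * p.value
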