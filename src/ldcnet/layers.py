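"""Minimal CNN layer engine (numpy, NHWC, float32).

Convolutions are evaluated by kernel-offset accumulation: for each of the
k*k kernel positions, a contiguous shifted slab of the input is multiplied
against a (Cin, Cout) weight matrix via BLAS GEMM.  This keeps the working
set small (no full im2col materialisation) and runs the whole forward and
backward pass through large matrix products, which is where single-core
throughput lives.  All layers implement analytic backprop; gradients are
verified against numerical differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "SoftmaxBinary",
    "Adam",
    "glorot_uniform",
]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x, *, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution, NHWC, stride 1, symmetric zero padding.

    Two GEMM strategies: thin inputs (small cin*k*k, e.g. the first layer's
    single channel) materialise the full im2col matrix — per-offset GEMMs
    would degenerate into memory-bound rank-1 updates there — while wide
    inputs accumulate one (Cin, Cout) GEMM per kernel offset, which avoids
    the k^2-fold im2col blow-up.  ``input_grad=False`` skips the input
    gradient (the first layer has no upstream to feed).
    """

    def __init__(self, cin: int, cout: int, kernel: int, pad: int,
                 rng: np.random.Generator, input_grad: bool = True):
        super().__init__()
        self.cin, self.cout, self.k, self.pad = cin, cout, kernel, pad
        self.input_grad = input_grad
        self._use_im2col = cin * kernel * kernel <= 128
        fan_in = kernel * kernel * cin
        fan_out = kernel * kernel * cout
        self.W = glorot_uniform(rng, (kernel, kernel, cin, cout), fan_in, fan_out)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def out_side(self, side: int) -> int:
        return side + 2 * self.pad - self.k + 1

    def _im2col(self, x, Ho, Wo):
        from numpy.lib.stride_tricks import sliding_window_view

        # (B, Ho, Wo, C, k, k) -> rows of (k, k, C) patches
        view = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        col = view.transpose(0, 1, 2, 4, 5, 3).reshape(-1, self.k * self.k * self.cin)
        return np.ascontiguousarray(col)

    def forward(self, x, *, train=False, rng=None):
        if self.pad:
            x = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad), (0, 0)))
        self._x_pad = x
        B, H, W, _ = x.shape
        Ho, Wo = H - self.k + 1, W - self.k + 1
        if self._use_im2col:
            col = self._im2col(x, Ho, Wo)
            self._col = col
            out = col @ self.W.reshape(-1, self.cout) + self.b
        else:
            out = np.tile(self.b, (B * Ho * Wo, 1))
            for di in range(self.k):
                for dj in range(self.k):
                    slab = np.ascontiguousarray(
                        x[:, di : di + Ho, dj : dj + Wo, :]
                    ).reshape(-1, self.cin)
                    out += slab @ self.W[di, dj]
        return out.reshape(B, Ho, Wo, self.cout)

    def backward(self, dout):
        x = self._x_pad
        B, H, W, _ = x.shape
        _, Ho, Wo, _ = dout.shape
        d2 = np.ascontiguousarray(dout).reshape(-1, self.cout)
        self.db[...] = d2.sum(axis=0)
        need_dx = self.input_grad
        dx = np.zeros_like(x) if need_dx else None
        if self._use_im2col:
            self.dW[...] = (self._col.T @ d2).reshape(self.W.shape)
            if need_dx:
                dcol = (d2 @ self.W.reshape(-1, self.cout).T).reshape(
                    B, Ho, Wo, self.k, self.k, self.cin
                )
                for di in range(self.k):
                    for dj in range(self.k):
                        dx[:, di : di + Ho, dj : dj + Wo, :] += dcol[:, :, :, di, dj, :]
            self._col = None
        else:
            for di in range(self.k):
                for dj in range(self.k):
                    slab = np.ascontiguousarray(
                        x[:, di : di + Ho, dj : dj + Wo, :]
                    ).reshape(-1, self.cin)
                    self.dW[di, dj] = slab.T @ d2
                    if need_dx:
                        dx[:, di : di + Ho, dj : dj + Wo, :] += (
                            d2 @ self.W[di, dj].T
                        ).reshape(B, Ho, Wo, self.cin)
        self._x_pad = None
        if not need_dx:
            return None
        if self.pad:
            dx = dx[:, self.pad : -self.pad, self.pad : -self.pad, :]
        return dx


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        # in place: the upstream layer keeps its own input, not its output
        self._mask = x > 0
        return np.maximum(x, 0.0, out=x)

    def backward(self, dout):
        dout[~self._mask] = 0.0
        return dout


class MaxPool2(Layer):
    """2x2 max pooling, stride 2, floor division (odd trailing row/col dropped)."""

    def forward(self, x, *, train=False, rng=None):
        B, H, W, C = x.shape
        Ho, Wo = H // 2, W // 2
        self._in_shape = x.shape
        xw = (
            x[:, : Ho * 2, : Wo * 2, :]
            .reshape(B, Ho, 2, Wo, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, Ho, Wo, 4, C)
        )
        self._argmax = xw.argmax(axis=3)
        return np.take_along_axis(xw, self._argmax[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]

    def backward(self, dout):
        B, H, W, C = self._in_shape
        Ho, Wo = H // 2, W // 2
        dxw = np.zeros((B, Ho, Wo, 4, C), dtype=dout.dtype)
        np.put_along_axis(dxw, self._argmax[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, : Ho * 2, : Wo * 2, :] = (
            dxw.reshape(B, Ho, Wo, 2, 2, C)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(B, Ho * 2, Wo * 2, C)
        )
        return dx


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = glorot_uniform(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.dW, self.db]

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout: active only in training mode, identity at inference."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class SoftmaxBinary(Layer):
    """Two-logit softmax head returning the positive-class probability."""

    def forward(self, logits, *, train=False, rng=None):
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        self._p = probs[:, 1]
        return self._p

    def backward(self, dp):
        pq = self._p * (1.0 - self._p)
        return (dp * pq)[:, None] * np.array([-1.0, 1.0], dtype=np.float32)


class Adam:
    """Adam optimizer over a flat list of (param, grad) array pairs."""

    def __init__(self, pairs, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.pairs = list(pairs)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.pairs]
        self.v = [np.zeros_like(p) for p, _ in self.pairs]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.pairs):
            m, v = self.m[i], self.v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
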