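"""Minimal CPU neural-network layers on numpy arrays.

All layers operate on float32 batches in NCHW layout. Each layer exposes
``forward(x, train)`` and ``backward(grad)``; learnable arrays are listed by
``params()`` as ``(name, value, grad)`` triples so the optimizer can update
them in place. The implementation favors BLAS-backed matmuls (im2col) over
explicit loops; transposed convolutions are realized as the exact adjoint of
the corresponding strided convolution, so encoder/decoder pairs stay
geometrically consistent.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers only need forward/backward."""

    def params(self):
        return []

    def forward(self, x, train=True):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError


def he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2D(Layer):
    """2-D correlation with kernel ``k``; padding 'valid' or 'same'."""

    def __init__(self, cin, cout, k, rng, padding="valid"):
        self.cin, self.cout, self.k = cin, cout, k
        self.padding = padding
        self.w = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train=True):
        k = self.k
        if self.padding == "same":
            p = k // 2
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, h, w = x.shape
        ho, wo = h - k + 1, w - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # n,c,ho,wo,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols, dtype=np.float32)
        y = cols @ self.w.reshape(self.cout, -1).T + self.b
        self._cols = cols
        self._xshape = (n, c, h, w)
        y = y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(y)

    def backward(self, grad):
        n, c, h, w = self._xshape
        k = self.k
        ho, wo = h - k + 1, w - k + 1
        g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.dw[...] = (g.T @ self._cols).reshape(self.w.shape)
        self.db[...] = g.sum(axis=0)
        # input gradient: scatter-add each kernel tap back to its input slice
        gc = (g @ self.w.reshape(self.cout, -1)).reshape(n, ho, wo, c, k, k)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dx[:, :, di:di + ho, dj:dj + wo] += gc[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        if self.padding == "same":
            p = k // 2
            dx = dx[:, :, p:h - p, p:w - p]
        self._cols = None
        return dx


class ConvTranspose2D(Layer):
    """Stride-2 transposed convolution (adjoint of a stride-2 correlation).

    Output size is ``stride*(H-1) + k`` — the exact transpose of the valid
    strided convolution, so a 3x3/stride-2 pair up-samples by ~2x.
    """

    def __init__(self, cin, cout, k, rng, stride=2):
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.w = he_init(rng, (cin, cout, k, k), cin * k * k)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def _out_size(self, h, w):
        s, k = self.stride, self.k
        return s * (h - 1) + k, s * (w - 1) + k

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        s, k = self.stride, self.k
        ho, wo = self._out_size(h, w)
        u = np.tensordot(x, self.w, axes=([1], [0]))  # n,h,w,cout,k,k
        y = np.zeros((n, self.cout, ho, wo), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                y[:, :, di:di + s * (h - 1) + 1:s, dj:dj + s * (w - 1) + 1:s] += \
                    u[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        y += self.b[None, :, None, None]
        self._x = x
        return y

    def backward(self, grad):
        x = self._x
        n, c, h, w = x.shape
        s, k = self.stride, self.k
        # gather the strided taps of grad that each input pixel touched
        taps = np.empty((n, self.cout, h, w, k, k), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                taps[:, :, :, :, di, dj] = grad[:, :, di:di + s * (h - 1) + 1:s,
                                                dj:dj + s * (w - 1) + 1:s]
        self.dw[...] = np.tensordot(x, taps, axes=([0, 2, 3], [0, 2, 3]))
        self.db[...] = grad.sum(axis=(0, 2, 3))
        dx = np.tensordot(taps, self.w, axes=([1, 4, 5], [1, 2, 3]))  # n,h,w,cin
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, :2 * h2, :2 * w2].reshape(n, c, h2, 2, w2, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._idx = xt.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return xt.max(axis=-1)

    def backward(self, grad):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        g = np.zeros((n, c, h2, w2, 4), dtype=np.float32)
        np.put_along_axis(g, self._idx[..., None], grad[..., None], axis=-1)
        g = g.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, :2 * h2, :2 * w2] = g.reshape(n, c, 2 * h2, 2 * w2)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0))

    def backward(self, grad):
        return np.where(self._mask, grad, np.float32(0))


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(c, dtype=np.float32)
        self.run_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean[...] = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var[...] = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv.astype(np.float32))
        return (self.gamma[None, :, None, None] * xhat +
                self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, grad):
        xhat, inv = self._cache
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.dgamma[...] = (grad * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = grad.sum(axis=(0, 2, 3))
        gxh = grad * self.gamma[None, :, None, None]
        dx = (gxh - gxh.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (gxh * xhat).mean(axis=(0, 2, 3), keepdims=True))
        dx *= inv[None, :, None, None]
        # mean subtraction above already divided by m via .mean
        self._cache = None
        return dx.astype(np.float32)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin, nout, rng):
        self.w = he_init(rng, (nin, nout), nin)
        self.b = np.zeros(nout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.dw[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        dx = grad @ self.w.T
        self._x = None
        return dx


class PadToInput(Layer):
    """Symmetrically zero-pads spatial maps back to a recorded target size.

    The no-padding encoder/decoder shrinks maps by a few pixels; this layer
    restores the input frame so output labels align pixelwise with the input.
    """

    def __init__(self):
        self.target = None  # (h, w), set by the network before forward

    def forward(self, x, train=True):
        th, tw = self.target
        n, c, h, w = x.shape
        ph, pw = th - h, tw - w
        if ph < 0 or pw < 0:
            raise ValueError("decoder output larger than input frame")
        self._pads = (ph // 2, ph - ph // 2, pw // 2, pw - pw // 2)
        t, b, l, r = self._pads
        return np.pad(x, ((0, 0), (0, 0), (t, b), (l, r)))

    def backward(self, grad):
        t, b, l, r = self._pads
        h, w = grad.shape[2], grad.shape[3]
        return grad[:, :, t:h - b, l:w - r]


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        out = []
        for i, layer in enumerate(self.layers):
            for name, v, g in layer.params():
                out.append((f"{i}.{name}", v, g))
        return out

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class SGDMomentum:
    """Classical SGD with momentum (velocity) updates."""

    def __init__(self, net, lr, momentum=0.9):
        self.net = net
        self.lr = lr
        self.momentum = momentum
        self.vel = {name: np.zeros_like(v) for name, v, _ in net.params()}

    def step(self):
        for name, v, g in self.net.params():
            vel = self.vel[name]
            vel *= self.momentum
            vel -= self.lr * g
            v += vel


def softmax(logits, axis=-1):
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits, labels, sample_weight=None):
    """Weighted mean cross-entropy over rows of ``logits`` (M, C).

    Returns ``(loss, grad)``; ``sample_weight`` (M,) rescales each row's
    contribution (weights are normalized to sum to 1).
    """
    p = softmax(logits.astype(np.float64), axis=1)
    m = logits.shape[0]
    eps = 1e-12
    logp = np.log(p[np.arange(m), labels] + eps)
    grad = p
    grad[np.arange(m), labels] -= 1.0
    if sample_weight is None:
        loss = -logp.mean()
        grad /= m
    else:
        w = np.asarray(sample_weight, dtype=np.float64)
        wsum = w.sum()
        loss = -(w * logp).sum() / wsum
        grad *= (w / wsum)[:, None]
    return float(loss), grad.astype(np.float32)
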