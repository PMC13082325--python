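"""Minimal NumPy neural-network layers with manual backpropagation.

Implements exactly the pieces the compact shuffle-block classifier
needs: dense/pointwise/3x3/depthwise convolutions, batch
normalization, ReLU, max/global-average pooling, channel shuffle, a
softmax cross-entropy head and an Adam optimizer.  Shapes follow the
(N, C, H, W) convention.  Every layer exposes ``forward(x, train)``,
``backward(dout)`` and parallel ``params`` / ``grads`` lists.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv2d", "DepthwiseConv2d", "BatchNorm2d", "ReLU",
    "MaxPool2x2", "GlobalAvgPool", "Dense", "Flatten", "ChannelShuffle",
    "Sequential", "softmax", "SoftmaxCrossEntropy", "Adam",
    "channel_shuffle",
]


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Layer):
    """Standard convolution, square kernel, zero padding."""

    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = _he_init(rng, (out_ch, in_ch, k, k), in_ch * k * k)
        self.b = np.zeros(out_ch)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xp.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        out = np.zeros((n, ho, wo, self.w.shape[0]))
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s]
                out += np.tensordot(patch, self.w[:, :, di, dj], axes=([1], [1]))
        out = out.transpose(0, 3, 1, 2) + self.b[None, :, None, None]
        self._cache = (xp, x.shape, ho, wo)
        return out

    def backward(self, dout):
        xp, xshape, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros_like(xp)
        d = dout.transpose(0, 2, 3, 1)          # (N, Ho, Wo, O)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s]
                # dW: sum over batch and spatial
                self.grads[0][:, :, di, dj] += np.tensordot(
                    d, patch, axes=([0, 1, 2], [0, 2, 3]))
                dxp[:, :, di:di + ho * s:s, dj:dj + wo * s:s] += np.tensordot(
                    d, self.w[:, :, di, dj], axes=([3], [0])
                ).transpose(0, 3, 1, 2)
        self.grads[1] += dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class DepthwiseConv2d(Layer):
    """Per-channel 2-D convolution (one filter per channel)."""

    def __init__(self, ch: int, k: int = 3, stride: int = 1, pad: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.k, self.stride, self.pad = k, stride, pad
        self.w = _he_init(rng, (ch, k, k), k * k)
        self.b = np.zeros(ch)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        k, s, p = self.k, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        n, c, hp, wp = xp.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        out = np.zeros((n, c, ho, wo))
        for di in range(k):
            for dj in range(k):
                out += xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s] \
                    * self.w[None, :, di, dj, None, None]
        out += self.b[None, :, None, None]
        self._cache = (xp, ho, wo)
        return out

    def backward(self, dout):
        xp, ho, wo = self._cache
        k, s, p = self.k, self.stride, self.pad
        dxp = np.zeros_like(xp)
        for di in range(k):
            for dj in range(k):
                patch = xp[:, :, di:di + ho * s:s, dj:dj + wo * s:s]
                self.grads[0][:, di, dj] += (dout * patch).sum(axis=(0, 2, 3))
                dxp[:, :, di:di + ho * s:s, dj:dj + wo * s:s] += \
                    dout * self.w[None, :, di, dj, None, None]
        self.grads[1] += dout.sum(axis=(0, 2, 3))
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class BatchNorm2d(Layer):
    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout):
        xhat, inv, shape = self._cache
        m = shape[0] * shape[2] * shape[3]
        self.grads[0] += (dout * xhat).sum(axis=(0, 2, 3))
        self.grads[1] += dout.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
              ) * inv[None, :, None, None]
        # note mean over (0,2,3) uses m elements per channel
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; truncates odd trailing rows/cols."""

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xt = x[:, :, :ho * 2, :wo * 2].reshape(n, c, ho, 2, wo, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._arg = xt.argmax(axis=-1)
        self._shape = x.shape
        return xt.max(axis=-1)

    def backward(self, dout):
        n, c, h, w = self._shape
        ho, wo = h // 2, w // 2
        dx4 = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(dx4, self._arg[..., None], dout[..., None], axis=-1)
        dx = dx4.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5) \
            .reshape(n, c, ho * 2, wo * 2)
        if (h, w) != (ho * 2, wo * 2):
            full = np.zeros((n, c, h, w))
            full[:, :, :ho * 2, :wo * 2] = dx
            return full
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = _he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads[0] += self._x.T @ dout
        self.grads[1] += dout.sum(axis=0)
        return dout @ self.w.T


def channel_shuffle(x: np.ndarray, groups: int) -> np.ndarray:
    """The reshape-transpose-flatten channel permutation.

    Channels are viewed as (groups, c/groups), transposed and
    flattened, interleaving channels across groups.  Works on (N, C)
    or (N, C, H, W) arrays.
    """
    c = x.shape[1]
    if c % groups:
        raise ValueError(f"{c} channels not divisible by {groups} groups")
    shape = x.shape
    xg = x.reshape(shape[0], groups, c // groups, *shape[2:])
    return np.swapaxes(xg, 1, 2).reshape(shape)


class ChannelShuffle(Layer):
    def __init__(self, groups: int):
        super().__init__()
        self.groups = groups

    def forward(self, x, train=True):
        self._c = x.shape[1]
        return channel_shuffle(x, self.groups)

    def backward(self, dout):
        # the inverse of a (g, c/g) shuffle is the (c/g, g) shuffle
        return channel_shuffle(dout, self._c // self.groups)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for lay in self.layers:
            self.params += lay.params
            self.grads += lay.grads

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, dout):
        for lay in reversed(self.layers):
            dout = lay.backward(dout)
        return dout


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class SoftmaxCrossEntropy:
    """Fused softmax + cross-entropy head."""

    def forward(self, logits: np.ndarray, labels: np.ndarray) -> float:
        self._p = softmax(logits)
        self._y = labels
        n = logits.shape[0]
        return float(-np.mean(np.log(self._p[np.arange(n), labels] + 1e-12)))

    def backward(self) -> np.ndarray:
        n = self._p.shape[0]
        d = self._p.copy()
        d[np.arange(n), self._y] -= 1.0
        return d / n


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list, grads: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def zero_grad(self):
        for g in self.grads:
            g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
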