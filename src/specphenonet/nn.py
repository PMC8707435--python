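"""Minimal numpy layer framework with reverse-mode gradients.

Implements exactly the pieces the two classifiers need: 1D/3D convolutions,
batch normalization, GELU/PReLU activations, dropout, max/average/adaptive
pooling, dense layers, softmax and an Adam optimizer.  Forward passes use
im2col via ``sliding_window_view``; backward passes are hand-derived.

Shape conventions: 1D tensors are (batch, channels, length); 3D tensors are
(batch, channels, depth, height, width).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))
_GELU_CUBIC = 0.044715


def gelu(x):
    """Gaussian-error linear unit, tanh approximation.

    ``0.5*x*(1 + tanh(sqrt(2/pi)*(x + 0.044715*x**3)))``
    """
    x = np.asarray(x, dtype=float)
    u = _SQRT_2_OVER_PI * (x + _GELU_CUBIC * x ** 3)
    out = 0.5 * x * (1.0 + np.tanh(u))
    return float(out) if out.ndim == 0 else out


def _gelu_grad(x):
    u = _SQRT_2_OVER_PI * (x + _GELU_CUBIC * x ** 3)
    t = np.tanh(u)
    du = _SQRT_2_OVER_PI * (1.0 + 3.0 * _GELU_CUBIC * x ** 2)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * du


class Param:
    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=float)
        self.grad = np.zeros_like(self.data)


class Layer:
    """Base layer; subclasses cache what backward needs during forward."""

    role: str | None = None

    def forward(self, x, training: bool = False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def parameters(self) -> list[Param]:
        return []


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, training: bool = False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


def walk(layer: Layer):
    """Depth-first iteration over primitive (non-container) layers."""
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from walk(sub)
    elif hasattr(layer, "sublayers"):
        for sub in layer.sublayers():
            yield from walk(sub)
    else:
        yield layer


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int, int]:
    out = -(-length // stride)
    total = max((out - 1) * stride + kernel - length, 0)
    return out, total // 2, total - total // 2


class Conv1d(Layer):
    role = "conv"

    def __init__(self, in_channels, out_channels, kernel, stride=1,
                 rng: np.random.Generator | None = None, role="conv"):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel, self.stride = kernel, stride
        self.role = role
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(out_channels, in_channels, kernel)))
        self.b = Param(np.zeros(out_channels))

    def forward(self, x, training=False):
        B, C, L = x.shape
        out, pl, pr = _same_pad(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        win = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride][:, :, :out]
        y = np.einsum("bcok,fck->bfo", win, self.W.data, optimize=True)
        y += self.b.data[:, None]
        self._cache = (win, xp.shape, pl, L)
        return y

    def backward(self, grad):
        win, xp_shape, pl, L = self._cache
        self.W.grad += np.einsum("bfo,bcok->fck", grad, win, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dxp = np.zeros(xp_shape)
        O = grad.shape[2]
        for k in range(self.kernel):
            contrib = np.einsum("bfo,fc->bco", grad, self.W.data[:, :, k], optimize=True)
            dxp[:, :, k:k + O * self.stride:self.stride] += contrib
        return dxp[:, :, pl:pl + L]

    def parameters(self):
        return [self.W, self.b]


class Conv3d(Layer):
    role = "conv"

    def __init__(self, in_channels, out_channels, kernel: tuple[int, int, int],
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel = tuple(kernel)
        fan_in = in_channels * int(np.prod(kernel))
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  size=(out_channels, in_channels, *kernel)))
        self.b = Param(np.zeros(out_channels))

    def forward(self, x, training=False):
        B, C, D, H, W_ = x.shape
        kd, kh, kw = self.kernel
        pads = [(k - 1) // 2 for k in self.kernel]
        pads_hi = [k - 1 - p for k, p in zip(self.kernel, pads)]
        xp = np.pad(x, ((0, 0), (0, 0),
                        (pads[0], pads_hi[0]), (pads[1], pads_hi[1]),
                        (pads[2], pads_hi[2])))
        win = sliding_window_view(xp, self.kernel, axis=(2, 3, 4))
        y = np.einsum("bcdhwijk,fcijk->bfdhw", win, self.W.data, optimize=True)
        y += self.b.data[None, :, None, None, None]
        self._cache = (win, xp.shape, pads, (D, H, W_))
        return y

    def backward(self, grad):
        win, xp_shape, pads, dims = self._cache
        self.W.grad += np.einsum("bfdhw,bcdhwijk->fcijk", grad, win, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3, 4))
        dxp = np.zeros(xp_shape)
        D, H, W_ = dims
        kd, kh, kw = self.kernel
        for i in range(kd):
            for j in range(kh):
                contrib = np.einsum("bfdhw,fck->bcdhwk", grad,
                                    self.W.data[:, :, i, j, :], optimize=True)
                for k in range(kw):
                    dxp[:, :, i:i + D, j:j + H, k:k + W_] += contrib[..., k]
        return dxp[:, :, pads[0]:pads[0] + D, pads[1]:pads[1] + H,
                   pads[2]:pads[2] + W_]

    def parameters(self):
        return [self.W, self.b]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis (1)."""

    role = "batchnorm"

    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.channels = channels
        self.momentum, self.eps = momentum, eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def _bshape(self, ndim):
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x, training=False):
        axes = (0,) + tuple(range(2, x.ndim))
        shp = self._bshape(x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shp)) * inv.reshape(shp)
        self._cache = (xhat, inv, axes, shp, training)
        return self.gamma.data.reshape(shp) * xhat + self.beta.data.reshape(shp)

    def backward(self, grad):
        xhat, inv, axes, shp, training = self._cache
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        scale = self.gamma.data.reshape(shp) * inv.reshape(shp)
        if not training:
            return grad * scale
        n = grad.size / self.channels
        return scale * (grad - dbeta.reshape(shp) / n - xhat * dgamma.reshape(shp) / n)

    def parameters(self):
        return [self.gamma, self.beta]


class GELU(Layer):
    role = "activation"

    def forward(self, x, training=False):
        self._x = x
        return gelu(x)

    def backward(self, grad):
        return grad * _gelu_grad(self._x)


class PReLU(Layer):
    """Parametric ReLU with one learnable slope per channel."""

    role = "activation"

    def __init__(self, channels, init=0.25):
        self.channels = channels
        self.a = Param(np.full(channels, init))

    def forward(self, x, training=False):
        shp = (1, self.channels) + (1,) * (x.ndim - 2)
        self._cache = (x, shp)
        return np.where(x > 0, x, self.a.data.reshape(shp) * x)

    def backward(self, grad):
        x, shp = self._cache
        axes = (0,) + tuple(range(2, x.ndim))
        neg = np.minimum(x, 0.0)
        self.a.grad += (grad * neg).sum(axis=axes)
        return np.where(x > 0, grad, self.a.data.reshape(shp) * grad)

    def parameters(self):
        return [self.a]


class Dropout(Layer):
    role = "dropout"

    def __init__(self, p=0.3, seed=0):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(seed)

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class AvgPool1d(Layer):
    role = "pool"

    def __init__(self, kernel=3):
        self.kernel = kernel

    def forward(self, x, training=False):
        B, C, L = x.shape
        O = L // self.kernel
        if O == 0:
            raise ValueError(f"length {L} too short for average pool kernel {self.kernel}")
        self._L = L
        return x[:, :, :O * self.kernel].reshape(B, C, O, self.kernel).mean(axis=3)

    def backward(self, grad):
        B, C, O = grad.shape
        dx = np.zeros((B, C, self._L))
        dx[:, :, :O * self.kernel] = np.repeat(grad / self.kernel, self.kernel, axis=2)
        return dx


class GlobalAvgPool1d(Layer):
    role = "pool"

    def forward(self, x, training=False):
        self._L = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._L, axis=2) / self._L


class MaxPool3d(Layer):
    """Max pooling with stride equal to the kernel (non-overlapping)."""

    role = "pool"

    def __init__(self, kernel: tuple[int, int, int]):
        self.kernel = tuple(kernel)

    def forward(self, x, training=False):
        B, C, D, H, W_ = x.shape
        kd, kh, kw = self.kernel
        Do, Ho, Wo = D // kd, H // kh, W_ // kw
        if min(Do, Ho, Wo) == 0:
            raise ValueError(f"input {x.shape} too small for maxpool kernel {self.kernel}")
        xr = (x[:, :, :Do * kd, :Ho * kh, :Wo * kw]
              .reshape(B, C, Do, kd, Ho, kh, Wo, kw)
              .transpose(0, 1, 2, 4, 6, 3, 5, 7)
              .reshape(B, C, Do, Ho, Wo, kd * kh * kw))
        self._idx = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        B, C, D, H, W_ = self._in_shape
        kd, kh, kw = self.kernel
        Do, Ho, Wo = D // kd, H // kh, W_ // kw
        z = np.zeros((B, C, Do, Ho, Wo, kd * kh * kw))
        np.put_along_axis(z, self._idx[..., None], grad[..., None], axis=-1)
        dx = np.zeros((B, C, D, H, W_))
        dx[:, :, :Do * kd, :Ho * kh, :Wo * kw] = (
            z.reshape(B, C, Do, Ho, Wo, kd, kh, kw)
             .transpose(0, 1, 2, 5, 3, 6, 4, 7)
             .reshape(B, C, Do * kd, Ho * kh, Wo * kw))
        return dx


class AdaptiveAvgPool3d(Layer):
    """Average pooling to a fixed output grid (handles any input size)."""

    role = "pool"

    def __init__(self, output: tuple[int, int, int]):
        self.output = tuple(output)

    @staticmethod
    def _bounds(size, out):
        return [(int(np.floor(i * size / out)), int(np.ceil((i + 1) * size / out)))
                for i in range(out)]

    def forward(self, x, training=False):
        B, C = x.shape[:2]
        od, oh, ow = self.output
        bd = self._bounds(x.shape[2], od)
        bh = self._bounds(x.shape[3], oh)
        bw = self._bounds(x.shape[4], ow)
        y = np.empty((B, C, od, oh, ow))
        for i, (d0, d1) in enumerate(bd):
            for j, (h0, h1) in enumerate(bh):
                for k, (w0, w1) in enumerate(bw):
                    y[:, :, i, j, k] = x[:, :, d0:d1, h0:h1, w0:w1].mean(axis=(2, 3, 4))
        self._cache = (x.shape, bd, bh, bw)
        return y

    def backward(self, grad):
        shape, bd, bh, bw = self._cache
        dx = np.zeros(shape)
        for i, (d0, d1) in enumerate(bd):
            for j, (h0, h1) in enumerate(bh):
                for k, (w0, w1) in enumerate(bw):
                    cnt = (d1 - d0) * (h1 - h0) * (w1 - w0)
                    dx[:, :, d0:d1, h0:h1, w0:w1] += (
                        grad[:, :, i, j, k][:, :, None, None, None] / cnt)
        return dx


class Flatten(Layer):
    role = "reshape"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear(Layer):
    role = "dense"

    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        self.in_features, self.out_features = in_features, out_features
        scale = np.sqrt(2.0 / in_features)
        self.W = Param(rng.normal(0.0, scale, size=(out_features, in_features)))
        self.b = Param(np.zeros(out_features))

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.data

    def parameters(self):
        return [self.W, self.b]


class Softmax(Layer):
    role = "softmax"

    def forward(self, x, training=False):
        z = x - x.max(axis=1, keepdims=True)
        e = np.exp(z)
        self._y = e / e.sum(axis=1, keepdims=True)
        return self._y

    def backward(self, grad):
        y = self._y
        return y * (grad - (grad * y).sum(axis=1, keepdims=True))


class Residual1dBlock(Layer):
    """Two kernel-7 convolutions with batch norm, GELU and a skip connection.

    The first convolution carries the block's stride; the skip path uses a
    kernel-1 projection (plus batch norm) whenever channels or stride change.
    """

    role = "residual"

    def __init__(self, in_channels, out_channels, kernel=7, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv1d(in_channels, out_channels, kernel, stride, rng=rng)
        self.bn1 = BatchNorm(out_channels)
        self.act1 = GELU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel, 1, rng=rng)
        self.bn2 = BatchNorm(out_channels)
        self.act2 = GELU()
        if in_channels != out_channels or stride != 1:
            self.proj = Conv1d(in_channels, out_channels, 1, stride,
                               rng=rng, role="projection")
            self.proj_bn = BatchNorm(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def sublayers(self):
        layers = [self.conv1, self.bn1, self.act1, self.conv2, self.bn2]
        if self.proj is not None:
            layers += [self.proj, self.proj_bn]
        return layers + [self.act2]

    def forward(self, x, training=False):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.act1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        if self.proj is not None:
            s = self.proj_bn.forward(self.proj.forward(x, training), training)
        else:
            s = x
        return self.act2.forward(h + s, training)

    def backward(self, grad):
        g = self.act2.backward(grad)
        gh = self.bn2.backward(g)
        gh = self.conv2.backward(gh)
        gh = self.act1.backward(gh)
        gh = self.bn1.backward(gh)
        gh = self.conv1.backward(gh)
        if self.proj is not None:
            gs = self.proj.backward(self.proj_bn.backward(g))
        else:
            gs = g
        return gh + gs

    def parameters(self):
        return [p for sub in self.sublayers() for p in sub.parameters()]


class Adam:
    """Adaptive-moment-estimation optimizer; ``lr`` is mutable for schedules."""

    def __init__(self, params: list[Param], lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
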