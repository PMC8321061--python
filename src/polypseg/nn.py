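"""Minimal NumPy CNN engine: layers with explicit forward/backward and Adam.

Everything operates on NCHW float arrays.  Layers cache what their backward
pass needs on ``forward`` and release it on ``backward``; parameters are
``Param`` objects holding ``data`` and accumulated ``grad``.  The engine
implements exactly the operations the dilated fully-convolutional
segmentation network needs: strided/dilated convolution (im2col + BLAS),
batch normalization, ReLU, 2x2 max pooling, dropout, fixed bilinear
upsampling, and a per-pixel softmax cross-entropy loss.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = np.ascontiguousarray(data)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    """Base layer; subclasses define forward/backward and expose params."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col / col2im


def conv_output_size(n: int, k: int, stride: int, pad: int, dilation: int = 1) -> int:
    eff = dilation * (k - 1) + 1
    return (n + 2 * pad - eff) // stride + 1


def _im2col(x, kh, kw, stride, pad, dilation):
    n, c, h, w = x.shape
    oh = conv_output_size(h, kh, stride, pad, dilation)
    ow = conv_output_size(w, kw, stride, pad, dilation)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            cols[:, :, i, j] = x[:, :, hi:hi + stride * oh:stride,
                                 wj:wj + stride * ow:stride]
    return cols.reshape(n, c * kh * kw, oh * ow), (oh, ow)

def _col2im(gcols, x_shape, kh, kw, stride, pad, dilation):
    n, c, h, w = x_shape
    oh = conv_output_size(h, kh, stride, pad, dilation)
    ow = conv_output_size(w, kw, stride, pad, dilation)
    gcols = gcols.reshape(n, c, kh, kw, oh, ow)
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=gcols.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            gx[:, :, hi:hi + stride * oh:stride,
               wj:wj + stride * ow:stride] += gcols[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


class Conv2d(Layer):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, dilation=1,
                 bias=True, rng=None, init="he", dtype=DTYPE):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad, self.dilation = kernel, stride, pad, dilation
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        fan_out = out_ch * kernel * kernel
        if init == "he":
            std = np.sqrt(2.0 / fan_in)
            w = rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel))
        else:  # xavier (glorot uniform)
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            w = rng.uniform(-limit, limit, (out_ch, in_ch, kernel, kernel))
        self.weight = Param(w.astype(dtype), "conv.weight")
        self.bias = Param(np.zeros(out_ch, dtype=dtype), "conv.bias") if bias else None
        self._cache = None

    @classmethod
    def same(cls, in_ch, out_ch, kernel, dilation=1, **kw):
        """Same-padding convolution (zero fill); odd kernels only."""
        if kernel % 2 == 0:
            raise ValueError("same-padding requires an odd kernel")
        return cls(in_ch, out_ch, kernel, stride=1,
                   pad=dilation * (kernel - 1) // 2, dilation=dilation, **kw)

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, training=False):
        k = self.kernel
        cols, (oh, ow) = _im2col(x, k, k, self.stride, self.pad, self.dilation)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        out = wmat @ cols  # (n, out_ch, oh*ow) via broadcasting over n
        out = out.reshape(x.shape[0], self.out_ch, oh, ow)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        self._cache = (cols, x.shape)
        return out

    def backward(self, grad):
        cols, x_shape = self._cache
        self._cache = None
        n = grad.shape[0]
        g2 = grad.reshape(n, self.out_ch, -1)
        wmat = self.weight.data.reshape(self.out_ch, -1)
        # weight grad: sum over batch of g2 @ cols^T
        gw = np.einsum("nop,ncp->oc", g2, cols, optimize=True)
        self.weight.grad += gw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=(0, 2))
        gcols = np.einsum("oc,nop->ncp", wmat, g2, optimize=True)
        k = self.kernel
        return _col2im(gcols, x_shape, k, k, self.stride, self.pad, self.dilation)


class BatchNorm2d(Layer):
    """Per-channel batch normalization over (N, H, W) with running statistics."""

    def __init__(self, n_ch, momentum=0.1, eps=1e-5, dtype=DTYPE):
        self.gamma = Param(np.ones(n_ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(n_ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(n_ch, dtype=dtype)
        self.running_var = np.ones(n_ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        self._cache = (xhat, inv, training, x.shape)
        return out

    def backward(self, grad):
        xhat, inv, training, shape = self._cache
        self._cache = None
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        if not training:
            return grad * g * inv[None, :, None, None]
        n = shape[0] * shape[2] * shape[3]
        gxhat = grad * g
        t1 = gxhat.sum(axis=(0, 2, 3), keepdims=True)
        t2 = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (gxhat - t1 / n - xhat * t2 / n) * inv[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    """2x2 stride-2 max pooling, floor semantics (trailing row/col dropped)."""

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        oh, ow = h // 2, w // 2
        xc = x[:, :, :2 * oh, :2 * ow].reshape(n, c, oh, 2, ow, 2)
        xw = xc.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, oh, ow, 4)
        self._arg = xw.argmax(axis=4)
        self._in_shape = x.shape
        return xw.max(axis=4)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        oh, ow = h // 2, w // 2
        gx4 = np.zeros((n, c, oh, ow, 4), dtype=grad.dtype)
        np.put_along_axis(gx4, self._arg[..., None], grad[..., None], axis=4)
        gx = np.zeros((n, c, h, w), dtype=grad.dtype)
        gx[:, :, :2 * oh, :2 * ow] = (
            gx4.reshape(n, c, oh, ow, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * oh, 2 * ow))
        self._arg = None
        return gx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. RNG is injected per forward."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        g = grad * self._mask
        self._mask = None
        return g


def _interp_matrix(n_out: int, n_in: int, dtype=DTYPE) -> np.ndarray:
    """Dense 1-D linear-interpolation matrix (align-corners mapping)."""
    m = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    pos = np.linspace(0.0, n_in - 1.0, n_out)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (pos - lo).astype(dtype)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


class BilinearUpsample(Layer):
    """Fixed (non-learned) bilinear upsampling to a target spatial size."""

    def __init__(self, out_h: int, out_w: int):
        self.out_h, self.out_w = out_h, out_w
        self._mats: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}

    def _get(self, h, w, dtype):
        key = (h, w)
        if key not in self._mats:
            self._mats[key] = (_interp_matrix(self.out_h, h, dtype),
                               _interp_matrix(self.out_w, w, dtype))
        return self._mats[key]

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        uh, uw = self._get(h, w, x.dtype)
        self._in_shape = x.shape
        y = np.einsum("Hh,nchw,Ww->ncHW", uh, x, uw, optimize=True)
        return np.ascontiguousarray(y)

    def backward(self, grad):
        n, c, h, w = self._in_shape
        uh, uw = self._get(h, w, grad.dtype)
        return np.ascontiguousarray(
            np.einsum("Hh,ncHW,Ww->nchw", uh, grad, uw, optimize=True))


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


# ---------------------------------------------------------------------------
# Loss


def softmax(scores: np.ndarray, axis: int = 1) -> np.ndarray:
    z = scores - scores.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(scores: np.ndarray, target: np.ndarray):
    """Per-pixel 2-class (or C-class) cross-entropy.

    scores: (N, C, H, W); target: (N, H, W) integer labels.
    Returns (mean loss, gradient wrt scores).
    """
    n, c, h, w = scores.shape
    p = softmax(scores, axis=1)
    flat = p.transpose(0, 2, 3, 1).reshape(-1, c)
    t = target.reshape(-1).astype(int)
    eps = 1e-12
    loss = -np.log(flat[np.arange(flat.shape[0]), t] + eps).mean()
    gflat = flat.copy()
    gflat[np.arange(flat.shape[0]), t] -= 1.0
    gflat /= flat.shape[0]
    grad = gflat.reshape(n, h, w, c).transpose(0, 3, 1, 2)
    return float(loss), np.ascontiguousarray(grad.astype(scores.dtype))


# ---------------------------------------------------------------------------
# Optimizer


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - b1) * (p.grad - m)
            v += (1.0 - b2) * (p.grad * p.grad - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
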