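"""Minimal NumPy neural-network layers for fully-convolutional models.

Tensors are NHWC float32.  Convolutions are evaluated as a sum of shifted
matrix products (one BLAS GEMM per kernel tap), which avoids the memory
blow-up of im2col while keeping all heavy arithmetic inside sgemm; the same
decomposition gives the exact gradients for weights and inputs.  Only what
the segmentation model needs is implemented: 2-D convolution (stride 1 or
more, 'same' padding), batch normalization, ReLU, nearest and bilinear
up-sampling, and the Adam optimizer.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self):
        return []

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


def he_normal(rng, shape, fan_in):
    """Variance-scaling (He) initialization for convolution kernels."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float32)


class Conv2d(Layer):
    """k x k convolution, 'same' padding for odd k, arbitrary stride."""

    def __init__(self, cin, cout, k=3, stride=1, bias=True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k - 1) // 2
        self.W = Param(he_normal(rng, (k, k, cin, cout), k * k * cin))
        self.b = Param(np.zeros(cout, dtype=np.float32)) if bias else None
        self._cache = None
        self._bufs = {}

    def _buffer(self, key, shape):
        buf = self._bufs.get(key)
        if buf is None or buf.shape != shape:
            buf = np.zeros(shape, dtype=np.float32)
            self._bufs[key] = buf
        return buf

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x, train=True):
        N, H, W, C = x.shape
        k, s, p = self.k, self.stride, self.pad
        Ho = (H + 2 * p - k) // s + 1
        Wo = (W + 2 * p - k) // s + 1
        if p:
            xp = self._buffer("xp", (N, H + 2 * p, W + 2 * p, C))
            xp[:, p:p + H, p:p + W, :] = x
        else:
            xp = x
        Wv = self.W.value
        y = np.zeros((N, Ho, Wo, self.cout), dtype=np.float32)
        if s == 1:
            # GEMM over the whole padded tensor per kernel tap, then
            # accumulate the shifted view: no input copies at all.
            Hp, Wp = xp.shape[1], xp.shape[2]
            xp2 = xp.reshape(-1, C)
            z2 = self._buffer("z", (xp2.shape[0], self.cout))
            z = z2.reshape(N, Hp, Wp, self.cout)
            for ki in range(k):
                for kj in range(k):
                    np.matmul(xp2, Wv[ki, kj], out=z2)
                    y += z[:, ki:ki + Ho, kj:kj + Wo, :]
        else:
            y2 = y.reshape(-1, self.cout)
            for ki in range(k):
                for kj in range(k):
                    xs = xp[:, ki:ki + s * Ho:s, kj:kj + s * Wo:s, :]
                    y2 += xs.reshape(-1, C) @ Wv[ki, kj]
        if self.b is not None:
            y += self.b.value
        if train:
            self._cache = (xp, x.shape, (N, Ho, Wo))
        else:
            self._cache = None
        return y

    def backward(self, dy):
        xp, xshape, (N, Ho, Wo) = self._cache
        k, s, p = self.k, self.stride, self.pad
        C = self.cin
        dy2 = np.ascontiguousarray(dy).reshape(-1, self.cout)
        if self.b is not None:
            self.b.grad += dy2.sum(axis=0)
        dxp = self._buffer("dxp", xp.shape)
        dxp.fill(0.0)
        Wv = self.W.value
        if s == 1:
            g2 = self._buffer("g", (dy2.shape[0], C))
            g = g2.reshape(N, Ho, Wo, C)
            for ki in range(k):
                for kj in range(k):
                    xs = xp[:, ki:ki + Ho, kj:kj + Wo, :]
                    self.W.grad[ki, kj] += xs.reshape(-1, C).T @ dy2
                    np.matmul(dy2, Wv[ki, kj].T, out=g2)
                    dxp[:, ki:ki + Ho, kj:kj + Wo, :] += g
        else:
            for ki in range(k):
                for kj in range(k):
                    sl = (slice(None), slice(ki, ki + s * Ho, s),
                          slice(kj, kj + s * Wo, s), slice(None))
                    xs = xp[sl]
                    self.W.grad[ki, kj] += xs.reshape(-1, C).T @ dy2
                    dxp[sl] += (dy2 @ Wv[ki, kj].T).reshape(N, Ho, Wo, C)
        self._cache = None
        if p:
            return dxp[:, p:p + xshape[1], p:p + xshape[2], :]
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, c, eps=1e-5, momentum=0.1, zero_scale=False):
        # zero_scale reproduces a literal gamma=0 initialization, which
        # zeroes every normalized activation at the start of training; the
        # standard gamma=1 is the default.
        self.gamma = Param(np.zeros(c, np.float32) if zero_scale
                           else np.ones(c, np.float32))
        self.beta = Param(np.zeros(c, np.float32))
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(c, np.float32)
        self.running_var = np.ones(c, np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        x2 = x.reshape(-1, x.shape[-1])
        m = x2.shape[0]
        if train:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat = x - mean.astype(np.float32)
        xhat *= inv_std
        if train:
            self._cache = (xhat, inv_std)
        y = xhat * self.gamma.value
        y += self.beta.value
        return y

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        dy2 = dy.reshape(-1, dy.shape[-1])
        xhat2 = xhat.reshape(-1, xhat.shape[-1])
        m = dy2.shape[0]
        s1 = dy2.sum(axis=0)
        s2 = (dy2 * xhat2).sum(axis=0)
        self.gamma.grad += s2
        self.beta.grad += s1
        g = self.gamma.value
        # dx = (g/std) * (dy - mean(dy) - xhat * mean(dy * xhat))
        a = (g * inv_std).astype(np.float32)
        dx = dy * a
        xh = xhat
        xh *= (a * s2 / m).astype(np.float32)  # xhat no longer needed
        dx -= xh
        dx -= (a * s1 / m).astype(np.float32)
        return dx


class ReLU(Layer):
    def forward(self, x, train=True):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy):
        mask, self._mask = self._mask, None
        dy = dy * mask
        return dy


class NearestUp2(Layer):
    """2x nearest-neighbor up-sampling (FPN top-down pathway)."""

    def forward(self, x, train=True):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy):
        N, H2, W2, C = dy.shape
        return dy.reshape(N, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    n_out = n_in * factor
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    lo = np.clip(i0, 0, n_in - 1)
    hi = np.clip(i0 + 1, 0, n_in - 1)
    A = np.zeros((n_out, n_in), dtype=np.float32)
    rows = np.arange(n_out)
    np.add.at(A, (rows, lo), (1.0 - frac).astype(np.float32))
    np.add.at(A, (rows, hi), frac.astype(np.float32))
    return A


class BilinearUp(Layer):
    """Integer-factor bilinear up-sampling via separable interpolation."""

    def __init__(self, factor: int):
        self.factor = factor
        self._mats = {}

    def _mat(self, n_in):
        if n_in not in self._mats:
            self._mats[n_in] = _interp_matrix(n_in, self.factor)
        return self._mats[n_in]

    def forward(self, x, train=True):
        A = self._mat(x.shape[1])
        B = self._mat(x.shape[2])
        self._shapes = (x.shape[1], x.shape[2])
        y = np.einsum("ph,nhwc->npwc", A, x, optimize=True)
        return np.einsum("qw,npwc->npqc", B, y,
                         optimize=True).astype(np.float32, copy=False)

    def backward(self, dy):
        A = self._mat(self._shapes[0])
        B = self._mat(self._shapes[1])
        d = np.einsum("qw,npqc->npwc", B, dy, optimize=True)
        return np.einsum("ph,npwc->nhwc", A, d,
                         optimize=True).astype(np.float32, copy=False)


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
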