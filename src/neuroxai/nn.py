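"""Minimal numpy kernels for small volumetric CNNs.

Implements exactly the pieces the decoder needs — strided 3D convolution with
"same" zero padding, batch normalization, a dense head, softmax cross-entropy
and Adam — with explicit forward/backward functions.  Keeping the backward
pass explicit (rather than relying on an autodiff framework) is what lets the
attribution module install non-standard backward rules (guided backprop,
DeepLift multipliers, LRP redistribution) without graph surgery.

All arrays are float64; volumes are laid out ``(batch, channels, D, H, W)``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "conv3d",
    "conv3d_input_grad",
    "conv3d_param_grad",
    "Conv3D",
    "BatchNorm3D",
    "Dense",
    "Adam",
    "softmax",
    "cross_entropy",
]


def _pad_amounts(n: int, k: int, stride: int) -> tuple[tuple[int, int], int]:
    """TensorFlow-style SAME padding: output length ceil(n/stride)."""
    out = -(-n // stride)
    total = max((out - 1) * stride + k - n, 0)
    return (total // 2, total - total // 2), out


def conv_output_shape(spatial: tuple[int, ...], k: int, stride: int) -> tuple[int, ...]:
    return tuple(_pad_amounts(n, k, stride)[1] for n in spatial)


def _pad_input(x: np.ndarray, ksizes, stride):
    pads, outs = [], []
    for n, k in zip(x.shape[2:], ksizes):
        (p0, p1), o = _pad_amounts(n, k, stride)
        pads.append((p0, p1))
        outs.append(o)
    xp = np.pad(x, ((0, 0), (0, 0), pads[0], pads[1], pads[2]))
    return xp, pads, tuple(outs)


def conv3d(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int) -> np.ndarray:
    """Strided 3D convolution (cross-correlation) with SAME zero padding.

    x: (B, Cin, D, H, W); w: (Cout, Cin, kd, kh, kw); b: (Cout,) or None.
    """
    kd, kh, kw = w.shape[2:]
    xp, _, (do, ho, wo) = _pad_input(x, (kd, kh, kw), stride)
    y = np.zeros((x.shape[0], w.shape[0], do, ho, wo), dtype=np.float64)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                xs = xp[:, :, i : i + stride * do : stride,
                        j : j + stride * ho : stride,
                        l : l + stride * wo : stride]
                y += np.einsum("kc,bcdhw->bkdhw", w[:, :, i, j, l], xs, optimize=True)
    if b is not None:
        y += b[None, :, None, None, None]
    return y


def conv3d_input_grad(dout: np.ndarray, w: np.ndarray, stride: int,
                      in_spatial: tuple[int, int, int]) -> np.ndarray:
    """Gradient of conv3d w.r.t. its input (a.k.a. transposed convolution)."""
    kd, kh, kw = w.shape[2:]
    pads, outs = [], []
    for n, k in zip(in_spatial, (kd, kh, kw)):
        (p0, p1), o = _pad_amounts(n, k, stride)
        pads.append((p0, p1))
        outs.append(o)
    do, ho, wo = outs
    b_sz, cin = dout.shape[0], w.shape[1]
    padded = tuple(n + p0 + p1 for n, (p0, p1) in zip(in_spatial, pads))
    dxp = np.zeros((b_sz, cin) + padded, dtype=np.float64)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                dxp[:, :, i : i + stride * do : stride,
                    j : j + stride * ho : stride,
                    l : l + stride * wo : stride] += np.einsum(
                    "kc,bkdhw->bcdhw", w[:, :, i, j, l], dout, optimize=True)
    sl = tuple(slice(p0, p0 + n) for n, (p0, _) in zip(in_spatial, pads))
    return dxp[(slice(None), slice(None)) + sl]


def conv3d_param_grad(dout: np.ndarray, x: np.ndarray, w_shape, stride: int):
    """Gradients of conv3d w.r.t. weights and bias."""
    kd, kh, kw = w_shape[2:]
    xp, _, (do, ho, wo) = _pad_input(x, (kd, kh, kw), stride)
    dw = np.zeros(w_shape, dtype=np.float64)
    for i in range(kd):
        for j in range(kh):
            for l in range(kw):
                xs = xp[:, :, i : i + stride * do : stride,
                        j : j + stride * ho : stride,
                        l : l + stride * wo : stride]
                dw[:, :, i, j, l] = np.einsum("bkdhw,bcdhw->kc", dout, xs, optimize=True)
    db = dout.sum(axis=(0, 2, 3, 4))
    return dw, db


class Conv3D:
    """3D convolution layer, He-normal initialised."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 2,
                 bias: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_ch * ksize ** 3
        self.w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                            size=(out_ch, in_ch, ksize, ksize, ksize))
        self.b = np.zeros(out_ch) if bias else None
        self.ksize = ksize
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        return conv3d(x, self.w, self.b, self.stride)

    def input_grad(self, dout: np.ndarray, in_spatial) -> np.ndarray:
        return conv3d_input_grad(dout, self.w, self.stride, in_spatial)

    def param_grad(self, dout: np.ndarray, x: np.ndarray):
        return conv3d_param_grad(dout, x, self.w.shape, self.stride)

    def params(self):
        return [self.w] if self.b is None else [self.w, self.b]


class BatchNorm3D:
    """Per-channel batch normalization for (B, C, D, H, W) tensors."""

    def __init__(self, n_ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool):
        if train:
            mu = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None, None]) * ivar[None, :, None, None, None]
        y = self.gamma[None, :, None, None, None] * xhat + self.beta[None, :, None, None, None]
        cache = (xhat, ivar)
        return y, cache

    def backward(self, dout: np.ndarray, cache):
        xhat, ivar = cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dgamma = (dout * xhat).sum(axis=(0, 2, 3, 4))
        dbeta = dout.sum(axis=(0, 2, 3, 4))
        dxhat = dout * self.gamma[None, :, None, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3, 4))[None, :, None, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3, 4))[None, :, None, None, None]
        dx = (ivar[None, :, None, None, None] / n) * (n * dxhat - s1 - xhat * s2)
        return dx, dgamma, dbeta

    def fold_into(self, w: np.ndarray, b: np.ndarray | None):
        """Return effective conv (w', b') with this BN (eval mode) absorbed."""
        scale = self.gamma / np.sqrt(self.running_var + self.eps)
        w_eff = w * scale[:, None, None, None, None]
        b0 = np.zeros(w.shape[0]) if b is None else b
        b_eff = (b0 - self.running_mean) * scale + self.beta
        return w_eff, b_eff

    def params(self):
        return [self.gamma, self.beta]


class Dense:
    """Fully connected layer: y = x @ W + b, W shaped (n_in, n_out)."""

    def __init__(self, n_in: int, n_out: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.W = rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out) if bias else None

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x @ self.W
        if self.b is not None:
            y = y + self.b
        return y

    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y_idx] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return float(loss), dlogits / n


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
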