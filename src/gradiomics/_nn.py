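"""Minimal numpy neural-network primitives for the test backbone.

Implements just what a small 2D CNN classifier needs: 3x3 same-padding
convolution via im2col, 2x2 max pooling, ReLU, global average pooling,
a dense layer, inverted dropout and Adam. Shapes follow the (N, C, H, W)
convention internally.
"""

from __future__ import annotations

import numpy as np

_K = 3  # all convolutions are 3x3, padding 1


def im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, 9*C, H*W) patch matrix for 3x3 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, _K * _K, c, h * w), dtype=x.dtype)
    for di in range(_K):
        for dj in range(_K):
            cols[:, di * _K + dj] = xp[:, :, di : di + h, dj : dj + w].reshape(n, c, h * w)
    return cols.reshape(n, _K * _K * c, h * w)


def col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`im2col`."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    d = dcols.reshape(n, _K * _K, c, h * w)
    for di in range(_K):
        for dj in range(_K):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, di * _K + dj].reshape(n, c, h, w)
    return dxp[:, :, 1:-1, 1:-1]


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * _K * _K))
        # weight layout (c_out, 9*c_in) matching im2col's (offset, channel) order
        self.w = rng.standard_normal((c_out, _K * _K * c_in)) * scale
        self.b = np.zeros(c_out)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        n, c, h, w = x.shape
        cols = im2col(x)
        out = np.matmul(self.w, cols) + self.b[:, None]
        if cache is not None:
            cache["cols"], cache["xshape"] = cols, x.shape
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray, cache: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n, _, h, w = dout.shape
        dflat = dout.reshape(n, self.c_out, h * w)
        dw = np.einsum("nfp,ncp->fc", dflat, cache["cols"])
        db = dflat.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, dflat)
        return col2im(dcols, cache["xshape"]), dw, db


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, out: np.ndarray) -> np.ndarray:
    return dout * (out > 0)


def maxpool2(x: np.ndarray, cache: dict | None = None) -> np.ndarray:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    if cache is not None:
        cache["idx"], cache["xshape"] = idx, x.shape
    return out


def maxpool2_backward(dout: np.ndarray, cache: dict) -> np.ndarray:
    n, c, h, w = cache["xshape"]
    idx = cache["idx"]
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.standard_normal((d_in, d_out)) * np.sqrt(2.0 / d_in)
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray, x: np.ndarray):
        return dout @ self.w.T, x.T @ dout, dout.sum(axis=0)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return float(loss), g / n


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
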