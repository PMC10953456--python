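"""Minimal CNN primitives (forward + backward) and the Adam optimizer.

Everything operates on float32 NCHW arrays.  Convolutions are expressed as a
sum over the 3x3 kernel positions, each a batched matrix product, which keeps
memory flat and is fast enough for the desk-scale image sizes this package
trains at.  Gradient correctness is pinned down by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_backward",
    "relu",
    "relu_backward",
    "pixel_shuffle",
    "pixel_unshuffle",
    "he_init",
    "Adam",
]


def he_init(rng: np.random.Generator, out_ch: int, in_ch: int, k: int = 3) -> np.ndarray:
    std = np.sqrt(2.0 / (in_ch * k * k))
    return (rng.normal(0.0, std, size=(out_ch, in_ch, k, k))).astype(np.float32)


def conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 1):
    """Same-style 2D convolution.  Returns (out, cache)."""
    n, c, h, wd = x.shape
    o, ci, kh, kw = w.shape
    assert ci == c, (ci, c)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (wd + 2 * pad - kw) // stride + 1
    out = np.broadcast_to(b[None, :, None, None], (n, o, ho, wo)).copy()
    for a in range(kh):
        for cc in range(kw):
            xs = xp[:, :, a: a + stride * ho: stride, cc: cc + stride * wo: stride]
            out += np.einsum("nchw,oc->nohw", xs, w[:, :, a, cc], optimize=True)
    return out, (xp, x.shape, w, stride, pad, ho, wo)


def conv2d_backward(dy: np.ndarray, cache):
    xp, xshape, w, stride, pad, ho, wo = cache
    o, c, kh, kw = w.shape
    dw = np.empty_like(w)
    db = dy.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for a in range(kh):
        for cc in range(kw):
            xs = xp[:, :, a: a + stride * ho: stride, cc: cc + stride * wo: stride]
            dw[:, :, a, cc] = np.einsum("nohw,nchw->oc", dy, xs, optimize=True)
            dxp[:, :, a: a + stride * ho: stride, cc: cc + stride * wo: stride] += (
                np.einsum("nohw,oc->nchw", dy, w[:, :, a, cc], optimize=True)
            )
    _, _, h, wd = xshape
    dx = dxp[:, :, pad: pad + h, pad: pad + wd]
    return dx, dw, db


def relu(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dy: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return dy * mask


def pixel_shuffle(x: np.ndarray, r: int = 2) -> np.ndarray:
    """[N, C*r*r, H, W] -> [N, C, H*r, W*r] (sub-pixel upsampling)."""
    n, crr, h, w = x.shape
    c = crr // (r * r)
    return (
        x.reshape(n, c, r, r, h, w)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, c, h * r, w * r)
    )


def pixel_unshuffle(x: np.ndarray, r: int = 2) -> np.ndarray:
    """Exact inverse (and adjoint) of pixel_shuffle."""
    n, c, hr, wr = x.shape
    h, w = hr // r, wr // r
    return (
        x.reshape(n, c, h, r, w, r)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, c * r * r, h, w)
    )


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v, "lr": self.lr}

    @classmethod
    def from_state(cls, state: dict, lr: float | None = None) -> "Adam":
        opt = cls(lr=lr if lr is not None else state.get("lr", 1e-4))
        opt.t = state["t"]
        opt.m = state["m"]
        opt.v = state["v"]
        return opt
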