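"""Compact numpy neural-network engine for image-to-image reconstruction.

Implements exactly the layer set the reconstruction networks need —
same-padded stride-1 convolutions (im2col), 2x2 max pooling, 2x2 stride-2
transposed convolutions, ReLU, per-channel batch normalization, channel
concatenation — with hand-written backward passes, an l1 loss and an Adam
optimizer.  Single-sample tensors are (C, H, W) float32; mini-batches are
handled by gradient accumulation in the training loop, matching the
batch-size-1 regime the method is trained in.

Everything is seeded through ``numpy.random.Generator``, so builds and
training runs are bit-reproducible on a fixed platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "ConvTranspose2x2", "MaxPool2x2", "ReLU", "BatchNorm2d",
           "Adam", "SGD", "l1_loss_and_grad"]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def params(self):
        return []

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0


class Conv2d(Layer):
    """Same-padded stride-1 convolution, He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self.k = kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p)))
        s0, s1, s2 = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp, shape=(c, k, k, h, w), strides=(s0, s1, s2, s1, s2))
        # (H*W, C*k*k)
        return view.transpose(3, 4, 0, 1, 2).reshape(h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        cols = self._im2col(np.ascontiguousarray(x))
        wmat = self.W.value.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b.value
        self._cache = (cols, (c, h, w))
        return np.ascontiguousarray(out.T.reshape(self.out_ch, h, w))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dmat = dout.reshape(self.out_ch, h * w).T  # (H*W, out)
        self.W.grad += (dmat.T @ cols).reshape(self.W.value.shape)
        self.b.grad += dout.sum(axis=(1, 2))
        dcols = dmat @ self.W.value.reshape(self.out_ch, -1)  # (H*W, C*k*k)
        dcols = dcols.reshape(h, w, c, k, k)
        dxp = np.zeros((c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for u in range(k):
            for v in range(k):
                dxp[:, u:u + h, v:v + w] += dcols[:, :, :, u, v].transpose(2, 0, 1)
        return dxp[:, p:p + h, p:p + w] if p else dxp


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 name: str = "upconv"):
        w = rng.normal(0.0, np.sqrt(2.0 / in_ch), size=(in_ch, out_ch, 2, 2))
        self.W = Param(w, f"{name}.W")
        self.b = Param(np.zeros(out_ch), f"{name}.b")
        self.in_ch, self.out_ch = in_ch, out_ch
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        out = np.empty((self.out_ch, 2 * h, 2 * w), dtype=DTYPE)
        for u in range(2):
            for v in range(2):
                out[:, u::2, v::2] = np.tensordot(
                    self.W.value[:, :, u, v], x, axes=(0, 0))
        out += self.b.value[:, None, None]
        self._cache = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._cache
        dx = np.zeros_like(x)
        for u in range(2):
            for v in range(2):
                d = dout[:, u::2, v::2]  # (out, H, W)
                self.W.grad[:, :, u, v] += np.tensordot(x, d, axes=([1, 2], [1, 2]))
                dx += np.tensordot(self.W.value[:, :, u, v], d, axes=(1, 0))
        self.b.grad += dout.sum(axis=(1, 2))
        return dx


class MaxPool2x2(Layer):
    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, h, w = x.shape
        xr = x.reshape(c, h // 2, 2, w // 2, 2).transpose(0, 1, 3, 2, 4)
        xr = np.ascontiguousarray(xr).reshape(c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=3)
        out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        self._cache = (idx, (c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (c, h, w) = self._cache
        dxr = np.zeros((c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
        dx = dxr.reshape(c, h // 2, w // 2, 2, 2).transpose(0, 1, 3, 2, 4)
        return np.ascontiguousarray(dx).reshape(c, h, w)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(DTYPE)


class BatchNorm2d(Layer):
    """Per-channel normalization over the spatial extent of the sample.

    Running statistics (momentum 0.1) are used at evaluation time.
    """

    def __init__(self, ch: int, name: str = "bn", eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = Param(np.ones(ch), f"{name}.gamma")
        self.beta = Param(np.zeros(ch), f"{name}.beta")
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(ch, dtype=DTYPE)
        self.running_var = np.ones(ch, dtype=DTYPE)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(1, 2))
            var = x.var(axis=(1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * inv[:, None, None]
        out = self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]
        self._cache = (xhat, inv, train)
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(1, 2))
        self.beta.grad += dout.sum(axis=(1, 2))
        g = self.gamma.value[:, None, None]
        if not train:
            return (dout * g * inv[:, None, None]).astype(DTYPE)
        m = xhat.shape[1] * xhat.shape[2]
        dxhat = dout * g
        dx = (dxhat - dxhat.mean(axis=(1, 2), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(1, 2), keepdims=True))
        return (dx * inv[:, None, None]).astype(DTYPE)


def l1_loss_and_grad(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error and its (sub)gradient w.r.t. ``pred``."""
    diff = pred - target
    loss = float(np.abs(diff).mean())
    grad = (np.sign(diff) / diff.size).astype(DTYPE)
    return loss, grad


class Adam:
    def __init__(self, params, lr: float = 0.005, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


class SGD:
    def __init__(self, params, lr: float = 0.005):
        self.params = list(params)
        self.lr = lr

    def step(self):
        for p in self.params:
            p.value -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
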