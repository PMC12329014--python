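"""Minimal CPU neural-network layers with explicit backprop.

The runtime environment provides no deep-learning framework, so the layers
the dual U-Net needs are implemented directly on numpy: 2-D convolution
(im2col + matmul), batch normalization, ReLU, 2x2 max pooling, stride-2
transposed convolution, and Adam with reduce-on-plateau scheduling.  All
tensors are NCHW float32; every layer owns its parameters and accumulates
gradients into them during ``backward``.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = [
    "Param",
    "Conv2D",
    "BatchNorm2D",
    "ReLU",
    "MaxPool2",
    "ConvTranspose2x2",
    "Adam",
    "ReduceLROnPlateau",
    "softmax",
    "cross_entropy",
    "weights_hash",
]


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*k*k) windows under 'same' zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # win: (N, C, H, W, k, k) -> (N, H, W, C*k*k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)


def _conv_same(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None):
    """'same' convolution; weight (cout, cin, k, k)."""
    n, c, h, w = x.shape
    cout, cin, k, _ = weight.shape
    col = _im2col(x, k)
    y = col @ weight.reshape(cout, -1).T
    if bias is not None:
        y += bias
    return y.reshape(n, h, w, cout).transpose(0, 3, 1, 2), col


class Conv2D(Layer):
    """3x3 (or 1x1) 'same' convolution, stride 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng=None, bias: bool = True):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.k = k
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y, col = _conv_same(x, self.w.value, self.b.value if self.b else None)
        if train:
            self._cache = (x.shape, col)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, col = self._cache
        n, cin, h, w = x_shape
        cout = dy.shape[1]
        dy_flat = dy.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.w.grad += (dy_flat.T @ col).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dy_flat.sum(axis=0)
        # dx = 'same' convolution of dy with the transposed, rotated kernel
        w_rot = self.w.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dx, _ = _conv_same(dy, np.ascontiguousarray(w_rot), None)
        return dx


class BatchNorm2D(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) * inv[None, :, None, None]
        return dx


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        y = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == y[:, :, :, None, :, None]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h2, w2 = dy.shape
        dyr = dy[:, :, :, None, :, None] * self._mask
        return dyr.reshape(n, c, h2 * 2, w2 * 2)


class ConvTranspose2x2(Layer):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / cin)
        self.w = Param(rng.normal(0.0, scale, size=(cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, cin, h, w = x.shape
        y = np.einsum("nihw,ioab->nohawb", x, self.w.value, optimize=True)
        y = y.reshape(n, -1, h * 2, w * 2) + self.b.value[None, :, None, None]
        if train:
            self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, cout, h2, w2 = dy.shape
        dyr = dy.reshape(n, cout, h2 // 2, 2, w2 // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        # dyr: (n, cout, h, w, 2, 2)
        self.w.grad += np.einsum("nihw,nohwab->ioab", x, dyr, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("nohwab,ioab->nihw", dyr, self.w.value, optimize=True)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, targets: np.ndarray):
    """Mean per-voxel CE of (N, C, H, W) probabilities vs integer targets.

    Returns (loss, dlogits) where the gradient is taken with respect to the
    pre-softmax logits.
    """
    n, c, h, w = probs.shape
    onehot = np.eye(c, dtype=probs.dtype)[targets].transpose(0, 3, 1, 2)
    eps = 1e-9
    loss = float(-(onehot * np.log(probs + eps)).sum() / (n * h * w))
    dlogits = (probs - onehot) / (n * h * w)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p in self.params:
            p.m = self.b1 * p.m + (1 - self.b1) * p.grad
            p.v = self.b2 * p.v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (p.m / b1t) / (np.sqrt(p.v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` when the metric stops improving."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 5,
                 min_lr: float = 1e-7):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad = 0

    def step(self, metric: float) -> None:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad = 0


def weights_hash(params: list[Param]) -> str:
    """SHA-256 over all parameter bytes (order-sensitive)."""
    h = hashlib.sha256()
    for p in params:
        h.update(np.ascontiguousarray(p.value).tobytes())
    return h.hexdigest()
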