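"""Minimal CPU neural-network engine (NCHW numpy tensors).

Provides exactly the layers the component U-Net needs — 2D convolution with
same-padding, batch normalization, ReLU, 2x2 max pooling with argmax indices,
max unpooling from stored indices — each with an explicit backward pass, plus
SGD with momentum and L2 weight decay.  Every backward pass is validated
against central-difference gradients in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "MaxUnpool2d",
    "SGD",
]


class Param:
    """A learnable tensor with gradient and momentum buffers.

    ``decay`` marks parameters subject to the L2 penalty lambda*||W||_F^2
    (convolution kernels); biases and batch-norm affine parameters are not
    penalized.
    """

    def __init__(self, value: np.ndarray, decay: bool = False):
        self.value = value
        self.grad = np.zeros_like(value)
        self.velocity = np.zeros_like(value)
        self.decay = decay

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Conv2d:
    """Same-padding 2D convolution via im2col + matmul."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel_size
        self.pad = kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        limit = np.sqrt(6.0 / fan_in)  # He-uniform fan-in
        w = rng.uniform(-limit, limit, size=(out_channels, in_channels,
                                             kernel_size, kernel_size))
        self.weight = Param(w.astype(dtype), decay=True)
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.weight, self.bias]

    def _im2col(self, xp: np.ndarray, H: int, W: int) -> np.ndarray:
        N, C = xp.shape[:2]
        K = self.k
        cols = np.empty((C, K * K, N, H, W), dtype=xp.dtype)
        for di in range(K):
            for dj in range(K):
                cols[:, di * K + dj] = xp[:, :, di:di + H, dj:dj + W].transpose(1, 0, 2, 3)
        return cols.reshape(C * K * K, N * H * W)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = self._im2col(xp, H, W)
        wmat = self.weight.value.reshape(self.cout, -1)
        y = wmat @ cols + self.bias.value[:, None]
        self._cols = cols if train else None
        self._xshape = (N, C, H, W)
        return y.reshape(self.cout, N, H, W).transpose(1, 0, 2, 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._xshape
        K, p = self.k, self.pad
        dyf = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)).reshape(self.cout, -1)
        self.weight.grad += (dyf @ self._cols.T).reshape(self.weight.value.shape)
        self.bias.grad += dyf.sum(axis=1)
        dcols = self.weight.value.reshape(self.cout, -1).T @ dyf
        view = dcols.reshape(C, K * K, N, H, W)
        dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dy.dtype)
        for di in range(K):
            for dj in range(K):
                dxp[:, :, di:di + H, dj:dj + W] += view[:, di * K + dj].transpose(1, 0, 2, 3)
        self._cols = None
        return dxp[:, :, p:p + H, p:p + W]


class BatchNorm2d:
    """Per-channel batch normalization.

    Training mode normalizes with batch statistics and updates running
    averages (momentum 0.1); inference mode uses the running averages.
    """

    def __init__(self, channels: int, dtype=np.float32,
                 eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            ivar = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * var
            self._cache = (xhat, ivar, x.shape)
        else:
            ivar = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean[None, :, None, None]) * ivar[None, :, None, None]
            self._cache = None
        return g * xhat + b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward requires a training-mode forward pass")
        xhat, ivar, shape = self._cache
        N, C, H, W = shape
        m = N * H * W
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = (ivar[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


def _pool_view(x: np.ndarray):
    """(N,C,H,W) -> (N,C,H/2,W/2,4) window view order (row-major in window)."""
    N, C, H, W = x.shape
    return (x.reshape(N, C, H // 2, 2, W // 2, 2)
             .transpose(0, 1, 2, 4, 3, 5)
             .reshape(N, C, H // 2, W // 2, 4))


def _unpool_view(xr: np.ndarray):
    """Inverse of :func:`_pool_view`."""
    N, C, Ho, Wo, _ = xr.shape
    return (xr.reshape(N, C, Ho, Wo, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(N, C, Ho * 2, Wo * 2))


class MaxPool2d:
    """2x2/stride-2 max pooling; stores argmax indices for unpooling."""

    def __init__(self):
        self.indices = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[2] % 2 or x.shape[3] % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {x.shape[2:]}")
        xr = _pool_view(x)
        self.indices = xr.argmax(axis=-1)
        return np.take_along_axis(xr, self.indices[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dxr = np.zeros(dy.shape + (4,), dtype=dy.dtype)
        np.put_along_axis(dxr, self.indices[..., None], dy[..., None], axis=-1)
        return _unpool_view(dxr)


class MaxUnpool2d:
    """Scatter each value back to the window position recorded by a pool layer."""

    def __init__(self):
        self._indices = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, indices: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape != indices.shape:
            raise ValueError("unpool input and indices must share shape")
        yr = np.zeros(x.shape + (4,), dtype=x.dtype)
        np.put_along_axis(yr, indices[..., None], x[..., None], axis=-1)
        self._indices = indices
        return _unpool_view(yr)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dyr = _pool_view(dy)
        return np.take_along_axis(dyr, self._indices[..., None], axis=-1)[..., 0]


class SGD:
    """Stochastic gradient descent with classical momentum.

    Weight decay enters as the exact gradient of lambda*||W||_F^2, i.e.
    2*lambda*W added to decayed parameters before the momentum update.
    """

    def __init__(self, params, lr: float, momentum: float = 0.95,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        for p in self.params:
            g = p.grad
            if p.decay and self.weight_decay:
                g = g + 2.0 * self.weight_decay * p.value
            p.velocity = self.momentum * p.velocity + g
            p.value -= self.lr * p.velocity
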