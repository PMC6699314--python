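"""A small self-contained NumPy CNN engine.

Implements exactly the layers the segmentation networks need — 2-D
convolution (same padding), batch normalization, ReLU, 2x2 max pooling,
2x2 stride-2 transposed convolution, dropout — with explicit forward and
backward passes, plus the Adam optimizer.  Tensors are channels-last
``(N, H, W, C)`` float32; convolutions reduce to a single BLAS matmul via
im2col.  Everything is deterministic given the generators passed in: there
is no global random state and no threading beyond BLAS.

Gradient correctness of every layer is validated by finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ContractError

F32 = np.float32


class Parameter:
    """A trainable array with its gradient accumulator.

    ``decay`` marks parameters subject to the L2 penalty (convolution
    kernels; biases and BN affine terms are exempt).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = False, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)
        self.decay = decay
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, same padding, He-initialized.

    Weight layout ``(k, k, c_in, c_out)``.  ``bias=False`` is used wherever
    batch normalization directly follows the convolution.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, bias: bool = True, name: str = ""):
        if k not in (1, 3):
            raise ContractError("only 1x1 and 3x3 convolutions are used here")
        std = np.sqrt(2.0 / (k * k * c_in))
        self.w = Parameter(rng.normal(0.0, std, (k, k, c_in, c_out)), decay=True, name=f"{name}.w")
        self.b = Parameter(np.zeros(c_out), name=f"{name}.b") if bias else None
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, h, w, c = x.shape
        k, p = self.k, self.k // 2
        self._xshape = x.shape
        if k == 1:
            cols = x.reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
            # blockwise im2col: column block (di, dj) holds the shifted image,
            # matching the (k, k, c_in) ordering of the flattened kernel
            cols = np.empty((n, h, w, k * k * c), dtype=F32)
            for di in range(k):
                for dj in range(k):
                    o = (di * k + dj) * c
                    cols[..., o : o + c] = xp[:, di : di + h, dj : dj + w, :]
            cols = cols.reshape(n * h * w, k * k * c)
        self._cols = cols if train else None
        y = cols @ self.w.value.reshape(k * k * c, self.c_out)
        if self.b is not None:
            y += self.b.value
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k, p, c = self.k, self.k // 2, self.c_in
        dyf = dy.reshape(-1, self.c_out)
        self.w.grad += (self._cols.T @ dyf).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.w.value.reshape(k * k * c, self.c_out).T
        if k == 1:
            return dcols.reshape(self._xshape)
        dcols = dcols.reshape(n, h, w, k * k * c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c), dtype=F32)
        for di in range(k):
            for dj in range(k):
                o = (di * k + dj) * c
                dxp[:, di : di + h, dj : dj + w, :] += dcols[..., o : o + c]
        return dxp[:, p : p + h, p : p + w, :]


class ConvTranspose2x2(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str = ""):
        std = np.sqrt(2.0 / c_in)  # each output pixel receives exactly one tap
        self.w = Parameter(rng.normal(0.0, std, (2, 2, c_in, c_out)), decay=True, name=f"{name}.w")
        self.b = Parameter(np.zeros(c_out), name=f"{name}.b")
        self.c_in, self.c_out = c_in, c_out
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, h, w, c = x.shape
        self._x = x if train else None
        self._xshape = x.shape
        y = np.empty((n, 2 * h, 2 * w, self.c_out), dtype=F32)
        xf = x.reshape(-1, c)
        for di in range(2):
            for dj in range(2):
                y[:, di::2, dj::2, :] = (xf @ self.w.value[di, dj]).reshape(n, h, w, self.c_out)
        y += self.b.value
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        xf = self._x.reshape(-1, c)
        dx = np.zeros((n * h * w, c), dtype=F32)
        self.b.grad += dy.sum(axis=(0, 1, 2))
        for di in range(2):
            for dj in range(2):
                dyf = np.ascontiguousarray(dy[:, di::2, dj::2, :]).reshape(-1, self.c_out)
                self.w.grad[di, dj] += xf.T @ dyf
                dx += dyf @ self.w.value[di, dj].T
        return dx.reshape(n, h, w, c)


class BatchNorm2d(Layer):
    """Batch normalization over (N, H, W) with affine parameters and running
    statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5, name: str = ""):
        self.gamma = Parameter(np.ones(channels), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(channels), name=f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * invstd
        if train:
            self._xhat, self._invstd = xhat.astype(F32), invstd.astype(F32)
        return (self.gamma.value * xhat + self.beta.value).astype(F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = dy.shape[0] * dy.shape[1] * dy.shape[2]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dy.sum(axis=(0, 1, 2))
        dxhat = dy * self.gamma.value
        dx = (invstd / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).sum(axis=(0, 1, 2))
        )
        return dx.astype(F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, F32(0.0))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, F32(0.0))


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ContractError(f"spatial size {(h, w)} not divisible by 2")
        r = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(
            n, h // 2, w // 2, c, 4
        )
        self._idx = r.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dr = np.zeros((n, h // 2, w // 2, c, 4), dtype=F32)
        np.put_along_axis(dr, self._idx[..., None], dy[..., None], axis=-1)
        return dr.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
            n, h, w, c
        )


class Dropout(Layer):
    """Inverted dropout; active only in training mode with a generator."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ContractError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._scale = 1.0

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ContractError("training-mode dropout needs a random generator")
        self._mask = (rng.random(x.shape) >= self.rate).astype(F32) / F32(1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_backward(probs: np.ndarray, dprobs: np.ndarray, axis: int = -1) -> np.ndarray:
    """Gradient through softmax given dL/dprobs."""
    inner = (dprobs * probs).sum(axis=axis, keepdims=True)
    return (probs * (dprobs - inner)).astype(F32)


class Adam:
    """Adam with the published default moments (beta1 0.9, beta2 0.999).

    The L2 penalty lambda * ||w||^2 / 2 on decay-flagged parameters is added
    to the loss gradient before the moment update (coupled weight decay, as
    when the penalty is part of the loss itself).
    """

    def __init__(self, params: list[Parameter], beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
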