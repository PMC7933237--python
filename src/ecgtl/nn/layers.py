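"""Basic 1D layers with explicit backward passes.

Signal tensors are shaped (batch, channels, length); feature tensors
(batch, features). Convolution uses column-unfolding (im2col) so the
heavy lifting is a single matrix product per layer.
"""

from __future__ import annotations

import numpy as np

from .core import Layer, Param


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
              dtype=np.float32) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _same_pad(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = -(-length // stride)  # ceil
    total = max((out - 1) * stride + kernel - length, 0)
    left = total // 2
    return left, total - left


def _unfold(xp: np.ndarray, kernel: int, stride: int, n_out: int) -> np.ndarray:
    """(B, C, Lp) -> (B, C, kernel, n_out) windows."""
    b, c, _ = xp.shape
    cols = np.empty((b, c, kernel, n_out), dtype=xp.dtype)
    for j in range(kernel):
        cols[:, :, j, :] = xp[:, :, j : j + stride * n_out : stride]
    return cols


def _fold_add(dxp: np.ndarray, dcols: np.ndarray, kernel: int, stride: int,
              n_out: int) -> None:
    for j in range(kernel):
        dxp[:, :, j : j + stride * n_out : stride] += dcols[:, :, j, :]


class Conv1d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: str = "same", bias: bool = False,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel
        self.w = Param(he_normal(rng, (out_channels, in_channels, kernel), fan_in, dtype),
                       name="conv_w")
        self.b = Param(np.zeros(out_channels, dtype=dtype), name="conv_b") if bias else None
        self._cache: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, length = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        if self.padding == "same":
            pl, pr = _same_pad(length, self.kernel, self.stride)
        else:
            pl = pr = 0
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr))) if (pl or pr) else x
        n_out = (xp.shape[-1] - self.kernel) // self.stride + 1
        cols = _unfold(xp, self.kernel, self.stride, n_out)
        w2 = self.w.data.reshape(self.out_channels, -1)
        y = np.einsum("of,bfl->bol", w2, cols.reshape(b, c * self.kernel, n_out),
                      optimize=True)
        if self.b is not None:
            y += self.b.data[None, :, None]
        if train:
            self._cache.append((cols, xp.shape, (pl, pr), length, n_out))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (pl, pr), length, n_out = self._cache.pop()
        b = dy.shape[0]
        cols2 = cols.reshape(b, self.in_channels * self.kernel, n_out)
        dw = np.einsum("bol,bfl->of", dy, cols2, optimize=True)
        self.w.grad += dw.reshape(self.w.data.shape)
        if self.b is not None:
            self.b.grad += dy.sum(axis=(0, 2))
        w2 = self.w.data.reshape(self.out_channels, -1)
        dcols = np.einsum("of,bol->bfl", w2, dy, optimize=True)
        dcols = dcols.reshape(b, self.in_channels, self.kernel, n_out)
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        _fold_add(dxp, dcols, self.kernel, self.stride, n_out)
        if pl or pr:
            return dxp[:, :, pl : pl + length]
        return dxp


class BatchNorm1d(Layer):
    """Per-channel normalisation over (batch, length) with running moments."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype), name="bn_gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), name="bn_beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self._cache: list[tuple] = []

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        y = self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]
        if train:
            self._cache.append((xhat, inv.astype(x.dtype)))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache.pop()
        b, _, length = dy.shape
        m = b * length
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2))
        self.beta.grad += dy.sum(axis=(0, 2))
        g = self.gamma.data[None, :, None]
        dxhat = dy * g
        dx = (inv[None, :, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True)
        )
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._cache: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._cache.append(x > 0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._cache.pop()
        return dy * mask


class MaxPool1d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: str = "same") -> None:
        self.kernel = kernel
        self.stride = stride
        self.padding = padding
        self._cache: list[tuple] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, length = x.shape
        if self.padding == "same":
            pl, pr = _same_pad(length, self.kernel, self.stride)
        else:
            pl = pr = 0
        fill = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else np.iinfo(x.dtype).min
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)), constant_values=fill) if (pl or pr) else x
        n_out = (xp.shape[-1] - self.kernel) // self.stride + 1
        cols = _unfold(xp, self.kernel, self.stride, n_out)
        arg = cols.argmax(axis=2)
        y = np.take_along_axis(cols, arg[:, :, None, :], axis=2)[:, :, 0, :]
        if train:
            self._cache.append((arg, xp.shape, (pl, pr), length, n_out))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        arg, xp_shape, (pl, pr), length, n_out = self._cache.pop()
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for j in range(self.kernel):
            mask = arg == j
            dxp[:, :, j : j + self.stride * n_out : self.stride] += dy * mask
        if pl or pr:
            return dxp[:, :, pl : pl + length]
        return dxp


class GlobalAvgPool(Layer):
    def __init__(self) -> None:
        self._cache: list[int] = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._cache.append(x.shape[-1])
        return x.mean(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        length = self._cache.pop()
        return np.repeat(dy[:, :, None], length, axis=2) / length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, dtype=np.float32) -> None:
        rng = rng or np.random.default_rng()
        self.w = Param(he_normal(rng, (in_features, out_features), in_features, dtype),
                       name="dense_w")
        self.b = Param(np.zeros(out_features, dtype=dtype), name="dense_b") if bias else None
        self._cache: list[np.ndarray] = []

    def params(self) -> list[Param]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = x @ self.w.data
        if self.b is not None:
            y = y + self.b.data
        if train:
            self._cache.append(x)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache.pop()
        xf = x.reshape(-1, x.shape[-1])
        dyf = dy.reshape(-1, dy.shape[-1])
        self.w.grad += xf.T @ dyf
        if self.b is not None:
            self.b.grad += dyf.sum(axis=0)
        return dy @ self.w.data.T


# ---------------------------------------------------------------- losses

def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray
                          ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and gradient wrt logits.

    ``targets`` are integer class indices, shape (batch,).
    """
    p = softmax(logits.astype(np.float64))
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(p[np.arange(n), targets] + eps).mean()
    dz = p
    dz[np.arange(n), targets] -= 1.0
    return float(loss), (dz / n).astype(logits.dtype)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_binary_cross_entropy(logits: np.ndarray, targets: np.ndarray
                                 ) -> tuple[float, np.ndarray]:
    """Mean element-wise binary cross-entropy and gradient wrt logits."""
    z = logits.astype(np.float64)
    # log(1+exp(-|z|)) formulation is stable for large |z|
    loss = np.maximum(z, 0) - z * targets + np.log1p(np.exp(-np.abs(z)))
    p = sigmoid(z)
    grad = (p - targets) / z.size
    return float(loss.mean()), grad.astype(logits.dtype)
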