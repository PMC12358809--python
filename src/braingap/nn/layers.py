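"""Minimal 3D neural-network layers with explicit forward/backward passes.

The layers operate on float32 arrays laid out as (N, C, D, H, W).  Each layer
caches what its backward pass needs during a training-mode forward call;
evaluation-mode forwards cache nothing.  Convolutions are computed as im2col
matrix products so the heavy lifting is done by BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ShapeError

__all__ = [
    "Parameter",
    "Layer",
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "Dropout",
    "Linear",
]


class Parameter:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Unfold (N,C,D,H,W) into (N, n_positions, C*k^3) patch rows."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    n, c, do, ho, wo = win.shape[:5]
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, do * ho * wo, c * k**3)
    return np.ascontiguousarray(cols, dtype=np.float32), (do, ho, wo)


class Conv3d(Layer):
    """3D convolution, stride 1, cubic kernel, symmetric zero padding.

    With kernel 3 / padding 1 the spatial size is preserved; kernel 1 /
    padding 0 gives the channel-wise (1x1x1) convolution.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 pad: int | None = None, rng: np.random.Generator | None = None,
                 name: str = "conv") -> None:
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = kernel // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        std = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.weight = Parameter(
            rng.normal(0.0, std, size=(c_out, c_in, kernel, kernel, kernel)),
            name=f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), name=f"{name}.bias")
        self._cols: np.ndarray | None = None
        self._out_spatial: tuple[int, int, int] | None = None
        self.compute_dx = True  # input-adjacent convs may skip the dx gather

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ShapeError(f"expected {self.c_in} input channels, got shape {x.shape}")
        cols, out_spatial = _im2col(x, self.k, self.pad)
        self._out_spatial = out_spatial
        self._cols = cols if train else None
        w = self.weight.value.reshape(self.c_out, -1)
        out = cols @ w.T + self.bias.value
        n = x.shape[0]
        return np.ascontiguousarray(
            out.transpose(0, 2, 1).reshape(n, self.c_out, *out_spatial))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c_out = dout.shape[:2]
        dmat = dout.reshape(n, c_out, -1).transpose(0, 2, 1)  # (N, L, c_out)
        cols = self._cols
        self.weight.grad += (
            dmat.reshape(-1, c_out).T @ cols.reshape(-1, cols.shape[-1])
        ).reshape(self.weight.value.shape)
        self.bias.grad += dmat.sum(axis=(0, 1))
        self._cols = None
        if not self.compute_dx:
            return np.empty(0, dtype=np.float32)
        # dx is a convolution of dout with the flipped kernel, channels swapped.
        # For stride 1 and pad = k//2 the same padding realizes the full conv.
        w_flip = self.weight.value[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        dcols, _ = _im2col(np.ascontiguousarray(dout, dtype=np.float32), self.k, self.pad)
        dx = dcols @ w_flip.reshape(self.c_in, -1).T
        do, ho, wo = self._out_spatial
        return np.ascontiguousarray(
            dx.transpose(0, 2, 1).reshape(n, self.c_in, do, ho, wo))


class BatchNorm3d(Layer):
    """Per-channel batch normalization with affine scale/shift.

    Running statistics use exponential averaging (momentum on the new value,
    unbiased variance), and are not trainable parameters.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.c = c
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(c), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(c), name=f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._xhat: np.ndarray | None = None
        self._std: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def _shape(self, v: np.ndarray) -> np.ndarray:
        return v.reshape(1, self.c, 1, 1, 1)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            n = x.size // self.c
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            unbiased = var * (n / max(n - 1, 1))
            self.running_var = ((1 - m) * self.running_var + m * unbiased).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - self._shape(mean)) / self._shape(std)
        if train:
            self._xhat, self._std = xhat, std
        return self._shape(self.gamma.value) * xhat + self._shape(self.beta.value)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, std = self._xhat, self._std
        self.beta.grad += dout.sum(axis=axes)
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        g = dout * self._shape(self.gamma.value)
        m1 = g.mean(axis=axes)
        m2 = (g * xhat).mean(axis=axes)
        dx = (g - self._shape(m1) - xhat * self._shape(m2)) / self._shape(std)
        self._xhat = self._std = None
        return dx.astype(np.float32)

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean.copy(),
                "running_var": self.running_var.copy()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.running_mean = state["running_mean"].copy()
        self.running_var = state["running_var"].copy()


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool3d(Layer):
    """2x2x2 max pooling with stride 2; trailing odd voxels are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, d, h, w = x.shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        if min(d2, h2, w2) < 1:
            raise ShapeError(f"spatial shape {(d, h, w)} too small for 2x pooling")
        xt = x[:, :, :2 * d2, :2 * h2, :2 * w2]
        xr = (xt.reshape(n, c, d2, 2, h2, 2, w2, 2)
                .transpose(0, 1, 2, 4, 6, 3, 5, 7)
                .reshape(n, c, d2, h2, w2, 8))
        arg = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg = arg
            self._in_shape = x.shape
        return np.ascontiguousarray(out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        d2, h2, w2 = d // 2, h // 2, w // 2
        dxr = np.zeros((n, c, d2, h2, w2, 8), dtype=np.float32)
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxt = (dxr.reshape(n, c, d2, h2, w2, 2, 2, 2)
                  .transpose(0, 1, 2, 5, 3, 6, 4, 7)
                  .reshape(n, c, 2 * d2, 2 * h2, 2 * w2))
        dx = np.zeros(self._in_shape, dtype=np.float32)
        dx[:, :, :2 * d2, :2 * h2, :2 * w2] = dxt
        self._arg = None
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N,C,D,H,W) -> (N,C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, d, h, w = self._in_shape
        scale = 1.0 / (d * h * w)
        return np.broadcast_to(
            (dout * scale)[:, :, None, None, None], self._in_shape
        ).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def reseed(self, seed_seq: np.random.SeedSequence) -> None:
        self.rng = np.random.default_rng(seed_seq)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


class Linear(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None,
                 name: str = "fc") -> None:
        rng = rng or np.random.default_rng(0)
        bound = np.sqrt(1.0 / c_in)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(c_out, c_in)),
                                name=f"{name}.weight")
        self.bias = Parameter(np.zeros(c_out), name=f"{name}.bias")

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        dx = dout @ self.weight.value
        self._x = None
        return dx
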