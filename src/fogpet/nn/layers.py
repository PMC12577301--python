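"""Minimal CNN building blocks with explicit backpropagation.

Convolutions use "same" padding (pad 1 for the 3x3(x3) kernels used here),
stride 1, and are evaluated as an im2col gather followed by a single BLAS
matrix multiply per batch, which keeps CPU training of small volumetric
networks tractable. Max pooling uses a 2^d window with stride 2 and routes
the gradient to the first maximal element of each window (fixed offset
order), so the gradient is conserved exactly even under ties.

Weights are initialized uniformly on +/- gain/sqrt(fan_in) with zero biases;
the default gain sqrt(6) is the He-uniform choice that preserves activation
variance through ReLU stacks. Model builders shrink the gain of the output
head so optimization starts from the class-prior solution.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

__all__ = [
    "Layer", "ConvND", "MaxPoolND", "ReLU", "Flatten", "Linear", "LogSoftmax",
    "nll_loss", "mse_loss",
]


class Layer:
    """Base layer: parameter/grad dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _uniform_init(rng: np.random.Generator, shape, fan_in: int, gain: float) -> np.ndarray:
    bound = gain / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class ConvND(Layer):
    """N-dimensional convolution (cross-correlation), kernel 3, stride 1, pad 1.

    ``init_gain`` scales the uniform init bound ``gain / sqrt(fan_in)``;
    ``sqrt(6)`` is the He-uniform choice that preserves activation variance
    through a ReLU.
    """

    def __init__(self, in_channels: int, out_channels: int, ndim: int, rng: np.random.Generator,
                 kernel: int = 3, init_gain: float = math.sqrt(6.0)) -> None:
        super().__init__()
        self.ndim, self.kernel = ndim, kernel
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.pad = kernel // 2
        fan_in = in_channels * kernel**ndim
        w_shape = (out_channels, in_channels) + (kernel,) * ndim
        self.params["W"] = _uniform_init(rng, w_shape, fan_in, init_gain)
        self.params["b"] = np.zeros(out_channels, dtype=np.float32)
        self._offsets = list(itertools.product(range(kernel), repeat=ndim))

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, C, *sp) -> contiguous (B, C*k^d, prod(sp)) column matrix."""
        B, C = x.shape[:2]
        spatial = x.shape[2:]
        pad_width = [(0, 0), (0, 0)] + [(self.pad, self.pad)] * self.ndim
        xp = np.pad(x, pad_width)
        K = len(self._offsets)
        cols = np.empty((B, C, K) + spatial, dtype=np.float32)
        for ki, off in enumerate(self._offsets):
            sl = tuple(slice(o, o + s) for o, s in zip(off, spatial))
            cols[:, :, ki] = xp[(slice(None), slice(None), *sl)]
        return cols.reshape(B, C * K, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x.astype(np.float32, copy=False)
        self._x_shape = x.shape
        self._spatial = x.shape[2:]
        self._cols = self._im2col(x)
        W = self.params["W"]
        Wmat = W.reshape(W.shape[0], -1)
        out = np.matmul(Wmat, self._cols)  # (B, out_ch, V)
        out += self.params["b"][None, :, None]
        return out.reshape(x.shape[0], W.shape[0], *self._spatial)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, O = dout.shape[:2]
        V = int(np.prod(self._spatial))
        doutm = dout.reshape(B, O, V).astype(np.float32, copy=False)
        Wmat = self.params["W"].reshape(O, -1)
        self.grads["W"] = np.tensordot(doutm, self._cols, axes=([0, 2], [0, 2])).reshape(
            self.params["W"].shape)
        self.grads["b"] = doutm.sum(axis=(0, 2))
        dcols = np.matmul(Wmat.T, doutm)  # (B, C*K, V)
        C = self._x_shape[1]
        K = len(self._offsets)
        dcols = dcols.reshape((B, C, K) + self._spatial)
        padded = tuple(s + 2 * self.pad for s in self._spatial)
        dxp = np.zeros((B, C, *padded), dtype=np.float32)
        for ki, off in enumerate(self._offsets):
            sl = tuple(slice(o, o + s) for o, s in zip(off, self._spatial))
            dxp[(slice(None), slice(None), *sl)] += dcols[:, :, ki]
        crop = tuple(slice(self.pad, self.pad + s) for s in self._spatial)
        del self._cols
        return dxp[(slice(None), slice(None), *crop)]


class MaxPoolND(Layer):
    """Max pooling with a 2^d window and stride 2 (spatial dims must be even)."""

    def __init__(self, ndim: int) -> None:
        super().__init__()
        self.ndim = ndim
        self._offsets = list(itertools.product((0, 1), repeat=ndim))

    def _views(self, x: np.ndarray):
        for off in self._offsets:
            yield x[(slice(None), slice(None)) + tuple(slice(o, None, 2) for o in off)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if any(s % 2 for s in x.shape[2:]):
            raise ValueError(f"spatial dims must be even for 2-pooling, got {x.shape[2:]}")
        self._x = x
        out = None
        for v in self._views(x):
            out = v.copy() if out is None else np.maximum(out, v, out=out)
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(self._x)
        taken = np.zeros(self._out.shape, dtype=bool)
        for xv, dxv in zip(self._views(self._x), self._views(dx)):
            sel = (xv == self._out) & ~taken
            dxv[sel] = dout[sel]
            taken |= sel
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 init_gain: float = math.sqrt(6.0)) -> None:
        super().__init__()
        self.params["W"] = _uniform_init(rng, (out_features, in_features), in_features, init_gain)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x.astype(np.float32, copy=False)
        return self._x @ self.params["W"].T + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout.astype(np.float32, copy=False)
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]


class LogSoftmax(Layer):
    """Row-wise log-softmax; outputs are log-probabilities."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = x - x.max(axis=1, keepdims=True)
        logz = np.log(np.exp(x).sum(axis=1, keepdims=True))
        self._logp = x - logz
        return self._logp

    def backward(self, dout: np.ndarray) -> np.ndarray:
        p = np.exp(self._logp)
        return (dout - p * dout.sum(axis=1, keepdims=True)).astype(np.float32, copy=False)


def nll_loss(logp: np.ndarray, targets: np.ndarray):
    """Mean negative log-likelihood of the true classes; returns (loss, dlogp)."""
    n = logp.shape[0]
    targets = np.asarray(targets, dtype=int)
    loss = float(-logp[np.arange(n), targets].mean())
    dlogp = np.zeros_like(logp)
    dlogp[np.arange(n), targets] = -1.0 / n
    return loss, dlogp


def mse_loss(pred: np.ndarray, targets: np.ndarray):
    """Mean squared error on scalar outputs; returns (loss, dpred)."""
    pred = pred.reshape(-1)
    targets = np.asarray(targets, dtype=np.float32).reshape(-1)
    err = pred - targets
    loss = float((err.astype(np.float64)**2).mean())
    dpred = (2.0 * err / len(err)).reshape(-1, 1).astype(np.float32)
    return loss, dpred
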