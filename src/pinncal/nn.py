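"""Minimal 1-D convolutional network building blocks with reverse-mode gradients.

Implemented directly on numpy: Conv1d ('same' padding, cross-correlation
convention), ReLU, MaxPool1d with stored argmax indices, MaxUnpool1d tied to
its matching pool, dense layers, and the ADAM optimiser.  Shapes follow the
(batch, channels, length) convention.  Every layer caches what its backward
pass needs during forward; gradients accumulate into ``Param.grad`` until
``zero_grad``.  All operations are plain vectorised numpy, so a fixed seed on
a fixed BLAS configuration reproduces training bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as _fft

__all__ = [
    "Param",
    "Conv1d",
    "ReLU",
    "MaxPool1d",
    "MaxUnpool1d",
    "Linear",
    "Flatten",
    "Adam",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class _Layer:
    def params(self) -> list[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0


class Conv1d(_Layer):
    """1-D convolution (cross-correlation) with 'same' output length.

    For kernel length K the input is padded (implicitly) by (K-1)//2 on the
    left and K//2 on the right, so output length equals input length and the
    pooling chain alone controls all downsampling.  Forward, input-gradient
    and weight-gradient passes are all evaluated as products in the Fourier
    domain (zero-padded real FFTs, so the convolution is exact, not
    circular); this is bit-deterministic and an order of magnitude faster
    than direct summation at these kernel sizes.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float64,
        init: str = "he",
        needs_input_grad: bool = True,
    ):
        self.needs_input_grad = needs_input_grad
        fan_in = in_channels * kernel
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel))
        elif init == "zero":
            w = np.zeros((out_channels, in_channels, kernel))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(out_channels, dtype=dtype))
        self.kernel = kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        n = _fft.next_fast_len(L + self.kernel)
        self._L, self._n = L, n
        X = _fft.rfft(x, n, axis=2)
        self._X = X
        # out[b,o,t] = sum_{i,j} W[o,i,j] x[b,i,t+j-pad_left]: correlate via
        # convolution with the reversed kernel, then shift by K-1-pad_left.
        Wf = _fft.rfft(self.W.value[:, :, ::-1], n, axis=2)
        y = _fft.irfft(np.einsum("bcf,ocf->bof", X, Wf, optimize=True), n, axis=2)
        start = self.kernel - 1 - self.pad_left
        out = np.ascontiguousarray(y[:, :, start : start + L])
        out += self.b.value[None, :, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        L, n = self._L, self._n
        self.b.grad += g.sum(axis=(0, 2), dtype=self.b.grad.dtype)
        Gf = _fft.rfft(g, n, axis=2)
        # dW[o,i,j] = sum_{b,t} g[b,o,t] x[b,i,t+j-pad_left]: a lagged
        # cross-correlation; negative lags wrap to the end of the buffer.
        q = _fft.irfft(
            np.einsum("bof,bcf->ocf", np.conj(Gf), self._X, optimize=True), n, axis=2
        )
        lags = (np.arange(self.kernel) - self.pad_left) % n
        self.W.grad += q[:, :, lags]
        if not self.needs_input_grad:
            return None  # first layer: nothing upstream consumes this
        Wf = _fft.rfft(self.W.value, n, axis=2)
        z = _fft.irfft(np.einsum("bof,ocf->bcf", Gf, Wf, optimize=True), n, axis=2)
        return np.ascontiguousarray(z[:, :, self.pad_left : self.pad_left + L])


class ReLU(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0)
        self._mask = out > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class MaxPool1d(_Layer):
    """Max pooling over fixed windows, remembering argmax positions.

    Windows start at multiples of ``stride``; any tail shorter than ``size``
    is dropped.  A stride larger than the window size is legal and simply
    skips the samples between windows.
    """

    def __init__(self, size: int, stride: int | None = None):
        self.size = size
        self.stride = stride if stride is not None else size

    def n_windows(self, length: int) -> int:
        if length < self.size:
            raise ValueError(f"input length {length} shorter than pool size {self.size}")
        return (length - self.size) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, L = x.shape
        n = self.n_windows(L)
        win = np.lib.stride_tricks.sliding_window_view(x, self.size, axis=2)[
            :, :, :: self.stride, :
        ][:, :, :n, :]
        arg = win.argmax(axis=3)
        pos = arg + (np.arange(n) * self.stride)[None, None, :]
        self._pos, self._in_shape = pos, (B, C, L)
        return np.take_along_axis(x, pos, axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape, dtype=g.dtype)
        B, C, _ = self._in_shape
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        if self.stride >= self.size:  # windows disjoint: positions are unique
            gx[bidx, cidx, self._pos] = g
        else:
            np.add.at(gx, (bidx, cidx, self._pos), g)
        return gx


class MaxUnpool1d(_Layer):
    """Scatter values back to the argmax positions of a matching pool layer.

    The pool's stored indices are treated as constants of the backward pass
    (the standard max-unpooling convention); the unpool output is zero away
    from those positions.
    """

    def __init__(self, pool: MaxPool1d):
        self.pool = pool

    def forward(self, x: np.ndarray) -> np.ndarray:
        pos, in_shape = self.pool._pos, self.pool._in_shape
        if x.shape != pos.shape:
            raise ValueError(
                f"unpool input shape {x.shape} does not match pooled shape {pos.shape}"
            )
        out = np.zeros(in_shape, dtype=x.dtype)
        B, C, _ = in_shape
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        out[bidx, cidx, pos] = x
        self._pos_cache = (bidx, cidx, pos)
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        bidx, cidx, pos = self._pos_cache
        return g[bidx, cidx, pos]


class Flatten(_Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g.reshape(self._shape)


class Linear(_Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        rng: np.random.Generator,
        dtype=np.float64,
        init: str = "he",
    ):
        if init == "he":
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        elif init == "zero":
            w = np.zeros((n_in, n_out))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.W = Param(w.astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ g
        self.b.grad += g.sum(axis=0)
        return g @ self.W.value.T


class Adam:
    """ADAM optimiser with bias-corrected first and second moments."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        for dst, src in zip(self.m, state["m"]):
            dst[...] = src
        for dst, src in zip(self.v, state["v"]):
            dst[...] = src
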