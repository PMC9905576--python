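"""The two-part physics-informed network: background autoencoder + concentration head.

The measured spectrum enters a convolutional autoencoder whose output is the
predicted background I_p,b.  The predicted background is subtracted from the
measurement and the residual enters a small convolutional + fully-connected
head that predicts the concentration vector c_p.  Nothing in the architecture
sees a concentration label; all supervision comes from the physics-informed
loss (see :mod:`pinncal.loss`).

Layer plan for the default 700-point grid (kernel length 20 throughout,
ReLU after every hidden convolution):

* encoder: conv(1->20) -> maxpool(10/10) -> conv(20->7) -> maxpool(14/14),
  giving a 7-channel x 5-position code;
* decoder: maxunpool(14/14) -> conv(7->7) -> conv(7->20) -> maxunpool(10/10)
  -> linear read-out conv(20->1) producing the background spectrum.  The
  unpool layers reuse the argmax indices stored by the matching encoder
  pools; the final read-out convolution collapses the 20 channels to the one
  output spectrum and is the only decoder layer without a rectifier.
* head: conv(1->5) -> maxpool(size 50, stride 100) -> dense(10, ReLU) ->
  dense(N, linear) on the background-subtracted spectrum.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np

from .nn import Conv1d, Flatten, Linear, MaxPool1d, MaxUnpool1d, Param, ReLU
from .spectra import ReferenceSet, Spectrum

__all__ = ["ModelConfig", "PinnModel", "PredictionResult", "build_model", "predict"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``head_pool_stride`` defaults to 100 with a window of 50, which skips
    every other 50-sample window; a contiguous variant (stride 50) is
    available through this field.
    """

    input_length: int = 700
    n_outputs: int = 1
    kernel: int = 20
    encoder_filters: tuple[int, int] = (20, 7)
    pool_sizes: tuple[int, int] = (10, 14)
    head_filters: int = 5
    head_pool_size: int = 50
    head_pool_stride: int = 100
    fc_width: int = 10
    dtype: str = "float32"
    #: multiplicative scaling applied to spectra before the first convolution
    #: (outputs and the loss stay in raw intensity units).  "auto" resolves to
    #: 1 / max(reference spectra) when training starts, so hidden activations
    #: are O(1) and ADAM's fixed-size steps translate into concentration
    #: updates at the 1e-3 scale; None disables scaling.
    input_scale: float | str | None = "auto"

    def __post_init__(self) -> None:
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be at least 1")
        block = self.pool_sizes[0] * self.pool_sizes[1]
        if self.input_length % block != 0 or self.input_length < block:
            lower = max(block, (self.input_length // block) * block)
            upper = lower + block
            raise ValueError(
                f"input length {self.input_length} is incompatible with the "
                f"pooling chain ({self.pool_sizes[0]} x {self.pool_sizes[1]}); "
                f"nearest compatible lengths are {lower} and {upper}"
            )
        if np.dtype(self.dtype) not in (np.dtype("float32"), np.dtype("float64")):
            raise ValueError("dtype must be float32 or float64")
        if isinstance(self.input_scale, str):
            if self.input_scale != "auto":
                raise ValueError("input_scale must be a positive number, 'auto' or None")
        elif self.input_scale is not None and self.input_scale <= 0:
            raise ValueError("input_scale must be a positive number, 'auto' or None")

    @property
    def code_shape(self) -> tuple[int, int]:
        """(channels, positions) at the autoencoder bottleneck."""
        return (
            self.encoder_filters[1],
            self.input_length // (self.pool_sizes[0] * self.pool_sizes[1]),
        )

    @property
    def head_features(self) -> int:
        n_windows = (self.input_length - self.head_pool_size) // self.head_pool_stride + 1
        return n_windows * self.head_filters


@dataclass
class PredictionResult:
    """Predicted concentrations with the decomposition the network implies."""

    concentrations: np.ndarray  # (n_outputs,) or (batch, n_outputs)
    background: Spectrum | list[Spectrum]
    agent: Spectrum | list[Spectrum]  # sum_j c_p,j * I0_j under the linear model


class PinnModel:
    """Differentiable map: measured spectrum -> (background, concentrations)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        # resolved multiplicative input scaling; None until "auto" is resolved
        # against a reference set (train does this), or permanently None when
        # scaling is disabled.
        self.input_scale: float | None = (
            float(config.input_scale)
            if isinstance(config.input_scale, (int, float))
            else None
        )
        rng = np.random.default_rng(seed)
        dt = np.dtype(config.dtype)
        k = config.kernel
        f1, f2 = config.encoder_filters

        self.conv1 = Conv1d(1, f1, k, rng, dt, needs_input_grad=False)
        self.relu1 = ReLU()
        self.pool1 = MaxPool1d(config.pool_sizes[0])
        self.conv2 = Conv1d(f1, f2, k, rng, dt)
        self.relu2 = ReLU()
        self.pool2 = MaxPool1d(config.pool_sizes[1])

        self.unpool2 = MaxUnpool1d(self.pool2)
        self.dconv1 = Conv1d(f2, f2, k, rng, dt)
        self.drelu1 = ReLU()
        self.dconv2 = Conv1d(f2, f1, k, rng, dt)
        self.drelu2 = ReLU()
        self.unpool1 = MaxUnpool1d(self.pool1)
        self.readout = Conv1d(f1, 1, k, rng, dt, init="zero")

        self.hconv = Conv1d(1, config.head_filters, k, rng, dt)
        self.hrelu = ReLU()
        self.hpool = MaxPool1d(config.head_pool_size, config.head_pool_stride)
        self.flatten = Flatten()
        self.fc1 = Linear(config.head_features, config.fc_width, rng, dt)
        self.frelu = ReLU()
        self.fc2 = Linear(config.fc_width, config.n_outputs, rng, dt, init="zero")

        self._layers = [
            self.conv1, self.relu1, self.pool1, self.conv2, self.relu2, self.pool2,
            self.unpool2, self.dconv1, self.drelu1, self.dconv2, self.drelu2,
            self.unpool1, self.readout,
            self.hconv, self.hrelu, self.hpool, self.flatten,
            self.fc1, self.frelu, self.fc2,
        ]

    # ------------------------------------------------------------------ core
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for layer in self._layers:
            out.extend(layer.params())
        return out

    def zero_grad(self) -> None:
        for layer in self._layers:
            layer.zero_grad()

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run a (batch, length) array through the network.

        Returns ``(background, concentrations)`` of shapes (batch, length)
        and (batch, n_outputs).
        """
        x = np.ascontiguousarray(x, dtype=self.config.dtype)
        if x.ndim != 2 or x.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected input of shape (batch, {self.config.input_length}), got {x.shape}"
            )
        s = self.input_scale if self.input_scale is not None else 1.0
        self._scale = s
        h = (x * s)[:, None, :] if s != 1.0 else x[:, None, :]
        h = self.relu1.forward(self.conv1.forward(h))
        h = self.pool1.forward(h)
        h = self.relu2.forward(self.conv2.forward(h))
        code = self.pool2.forward(h)

        h = self.unpool2.forward(code)
        h = self.drelu1.forward(self.dconv1.forward(h))
        h = self.drelu2.forward(self.dconv2.forward(h))
        h = self.unpool1.forward(h)
        bg = self.readout.forward(h)[:, 0, :]

        r = (x - bg) * s if s != 1.0 else x - bg
        h = self.hrelu.forward(self.hconv.forward(r[:, None, :]))
        h = self.hpool.forward(h)
        h = self.frelu.forward(self.fc1.forward(self.flatten.forward(h)))
        c = self.fc2.forward(h)
        return bg, c

    def backward(self, d_conc: np.ndarray, d_background: np.ndarray) -> None:
        """Accumulate parameter gradients of a scalar loss.

        ``d_conc`` and ``d_background`` are the loss gradients with respect to
        the two outputs of :meth:`forward`.  The background-subtracted
        residual couples the two paths: gradient flowing into the head input
        re-enters the decoder with a minus sign.
        """
        g = self.fc2.backward(np.ascontiguousarray(d_conc, dtype=self.config.dtype))
        g = self.fc1.backward(self.frelu.backward(g))
        g = self.hpool.backward(self.flatten.backward(g))
        g = self.hconv.backward(self.hrelu.backward(g))
        # head input is scale * (x - background), so its gradient re-enters
        # the background path multiplied by -scale
        g_bg = np.asarray(d_background, dtype=self.config.dtype) - self._scale * g[:, 0, :]

        g = self.readout.backward(g_bg[:, None, :])
        g = self.unpool1.backward(g)
        g = self.dconv2.backward(self.drelu2.backward(g))
        g = self.dconv1.backward(self.drelu1.backward(g))
        g = self.unpool2.backward(g)

        g = self.pool2.backward(g)
        g = self.conv2.backward(self.relu2.backward(g))
        g = self.pool1.backward(g)
        self.conv1.backward(self.relu1.backward(g))

    def resolve_input_scale(self, references: ReferenceSet) -> float:
        """Fix "auto" scaling to 1 / max(reference intensity); idempotent."""
        if self.input_scale is None and self.config.input_scale == "auto":
            peak = float(np.abs(references.matrix).max())
            if peak <= 0:
                raise ValueError("cannot derive input scaling from an all-zero reference")
            self.input_scale = 1.0 / peak
        return self.input_scale if self.input_scale is not None else 1.0

    # ------------------------------------------------------------ persistence
    def state_arrays(self) -> list[np.ndarray]:
        return [p.value for p in self.parameters()]

    def save(self, path) -> None:
        """Write a versioned checkpoint that round-trips config + weights bit-exactly."""
        payload = {f"param_{i:03d}": p.value for i, p in enumerate(self.parameters())}
        header = json.dumps(
            {
                "version": _CHECKPOINT_VERSION,
                "seed": self.seed,
                "config": asdict(self.config),
                "input_scale": self.input_scale,
            }
        )
        np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8), **payload)

    @classmethod
    def load(cls, path) -> "PinnModel":
        try:
            with np.load(path) as data:
                header = json.loads(bytes(data["_header"]).decode())
                if header.get("version") != _CHECKPOINT_VERSION:
                    raise ValueError(f"unsupported checkpoint version {header.get('version')}")
                cfg_dict = dict(header["config"])
                for key in ("encoder_filters", "pool_sizes"):
                    cfg_dict[key] = tuple(cfg_dict[key])
                model = cls(ModelConfig(**cfg_dict), seed=header.get("seed", 0))
                if header.get("input_scale") is not None:
                    model.input_scale = float(header["input_scale"])
                params = model.parameters()
                for i, p in enumerate(params):
                    arr = data[f"param_{i:03d}"]
                    if arr.shape != p.value.shape:
                        raise ValueError("checkpoint weight shapes do not match config")
                    p.value[...] = arr
        except (OSError, KeyError, ValueError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
            raise ValueError(f"cannot read model checkpoint {path!r}: {exc}") from exc
        return model


def build_model(config: ModelConfig, seed: int = 0) -> PinnModel:
    """Construct a randomly initialised network for the given architecture."""
    return PinnModel(config, seed=seed)


def predict(
    model: PinnModel,
    spectrum: Spectrum | np.ndarray,
    references: ReferenceSet,
) -> PredictionResult:
    """Predict concentrations and the background for one spectrum or a batch.

    The agent spectrum is reconstructed from the linear model,
    I_p,d = sum_j c_p,j * I0_j.
    """
    single = isinstance(spectrum, Spectrum)
    if single:
        if spectrum.grid != references.grid:
            raise ValueError("spectrum and references are on different grids")
        batch = spectrum.intensities[None, :]
    else:
        batch = np.atleast_2d(np.asarray(spectrum, dtype=float))
    if batch.shape[1] != references.grid.n_points:
        raise ValueError("spectrum length does not match the reference grid")
    if batch.shape[1] != model.config.input_length:
        raise ValueError(
            f"model expects {model.config.input_length}-point spectra, got {batch.shape[1]}"
        )
    if references.n_agents != model.config.n_outputs:
        raise ValueError("reference set size does not match the model's output width")

    bg, c = model.forward(batch)
    bg = bg.astype(float)
    c = c.astype(float)
    agent = c @ references.matrix
    grid = references.grid
    if single:
        return PredictionResult(
            concentrations=c[0],
            background=Spectrum(grid, bg[0]),
            agent=Spectrum(grid, agent[0]),
        )
    return PredictionResult(
        concentrations=c,
        background=[Spectrum(grid, row) for row in bg],
        agent=[Spectrum(grid, row) for row in agent],
    )
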