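"""Unsupervised training of the physics-informed network with ADAM.

Training minimises the physics-informed loss over measured spectra only;
concentration labels, even when present in a :class:`SyntheticDataset`, are
never read (the unsupervised contract).  With a fixed seed, single-threaded
numpy and an unchanged configuration, a run is bit-reproducible, and a run
of N epochs equals a run of M epochs resumed for N - M: checkpoints carry
the model weights, the ADAM moments, the shuffling RNG state and the loss
history.
"""

from __future__ import annotations

import json
import time
import zipfile
from dataclasses import dataclass, asdict, replace

import numpy as np

from .loss import alpha_heuristic, loss_gradients, LossBreakdown
from .model import ModelConfig, PinnModel
from .spectra import ReferenceSet
from .synthetic import SyntheticDataset

__all__ = ["TrainingConfig", "TrainingHistory", "train", "resume", "save_checkpoint"]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters.

    ``batch_size`` is the mini-batch size (default 100); set
    ``batch_mode="count"`` to reinterpret the same number as a number of
    batches per epoch instead.  ``alpha="auto"`` resolves the
    regularisation weight from the reference spectra before the first step.
    ``epochs`` defaults to the single-agent benchmark setting (5e3); the
    two-agent benchmark used 5e4.
    """

    epochs: int = 5000
    batch_size: int = 100
    batch_mode: str = "size"  # "size" | "count"
    learning_rate: float = 1e-3
    alpha: float | str = "auto"
    seed: int = 0
    checkpoint_interval: int = 0
    checkpoint_path: str | None = None
    patience: int | None = None  # early stopping, off by default

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch size must be at least 1")
        if self.batch_mode not in ("size", "count"):
            raise ValueError("batch_mode must be 'size' or 'count'")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if isinstance(self.alpha, str):
            if self.alpha != "auto":
                raise ValueError("alpha must be a non-negative number or 'auto'")
        elif self.alpha < 0:
            raise ValueError("alpha must be a non-negative number or 'auto'")

    def resolve_alpha(self, references: ReferenceSet) -> float:
        return alpha_heuristic(references) if self.alpha == "auto" else float(self.alpha)


@dataclass
class TrainingHistory:
    """Per-epoch loss terms (batch-averaged) and wall time."""

    reconstruction: np.ndarray
    smoothness: np.ndarray
    total: np.ndarray
    seconds: np.ndarray
    alpha: float

    @property
    def epochs_run(self) -> int:
        return int(self.total.size)

    def breakdown(self, epoch: int) -> LossBreakdown:
        return LossBreakdown(
            reconstruction=float(self.reconstruction[epoch]),
            smoothness=float(self.smoothness[epoch]),
            alpha=self.alpha,
            total=float(self.total[epoch]),
        )

    @staticmethod
    def concatenate(parts: list["TrainingHistory"]) -> "TrainingHistory":
        return TrainingHistory(
            np.concatenate([p.reconstruction for p in parts]),
            np.concatenate([p.smoothness for p in parts]),
            np.concatenate([p.total for p in parts]),
            np.concatenate([p.seconds for p in parts]),
            parts[-1].alpha,
        )

    def to_table(self) -> str:
        lines = ["epoch\tloss_rec\tloss_reg\tloss_tot\tseconds"]
        for i in range(self.epochs_run):
            lines.append(
                f"{i + 1}\t{self.reconstruction[i]:.8g}\t{self.smoothness[i]:.8g}"
                f"\t{self.total[i]:.8g}\t{self.seconds[i]:.4g}"
            )
        return "\n".join(lines) + "\n"


def _extract_spectra(data) -> np.ndarray:
    if isinstance(data, SyntheticDataset):
        return data.measured
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    return arr


def _extract_references(data, references: ReferenceSet | None) -> ReferenceSet:
    if references is not None:
        return references
    if isinstance(data, SyntheticDataset):
        return data.references
    raise ValueError("a ReferenceSet is required when the dataset carries none")


def _batch_size(config: TrainingConfig, n: int) -> int:
    if config.batch_mode == "size":
        return min(config.batch_size, n)
    return max(1, int(np.ceil(n / config.batch_size)))


def _run_epochs(
    model: PinnModel,
    X: np.ndarray,
    R: np.ndarray,
    spacing: float,
    alpha: float,
    config: TrainingConfig,
    optimizer,
    rng: np.random.Generator,
    n_epochs: int,
    log_every: int | None = None,
) -> TrainingHistory:
    n = X.shape[0]
    bs = _batch_size(config, n)
    rec = np.empty(n_epochs)
    reg = np.empty(n_epochs)
    tot = np.empty(n_epochs)
    secs = np.empty(n_epochs)
    for epoch in range(n_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(n)
        e_rec = e_reg = e_tot = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb = X[idx]
            bg, c = model.forward(xb)
            breakdown, d_c, d_bg = loss_gradients(xb, c, R, bg, alpha, spacing)
            model.zero_grad()
            model.backward(d_c, d_bg)
            optimizer.step()
            e_rec += breakdown.reconstruction
            e_reg += breakdown.smoothness
            e_tot += breakdown.total
            n_batches += 1
        rec[epoch] = e_rec / n_batches
        reg[epoch] = e_reg / n_batches
        tot[epoch] = e_tot / n_batches
        secs[epoch] = time.perf_counter() - t0
        if log_every and (epoch + 1) % log_every == 0:
            print(
                f"epoch {epoch + 1}/{n_epochs}  L_rec={rec[epoch]:.6g}  "
                f"L_reg={reg[epoch]:.6g}  L_tot={tot[epoch]:.6g}"
            )
    return TrainingHistory(rec, reg, tot, secs, alpha)


def train(
    model: PinnModel,
    data,
    references: ReferenceSet | None = None,
    config: TrainingConfig = TrainingConfig(),
    log_every: int | None = None,
) -> tuple[PinnModel, TrainingHistory]:
    """Minimise the physics-informed loss over a set of measured spectra.

    ``data`` may be a :class:`SyntheticDataset` (labels ignored) or a plain
    (n_samples, n_points) array.  The model is updated in place and also
    returned.
    """
    X = _extract_spectra(data)
    refs = _extract_references(data, references)
    if X.shape[1] != model.config.input_length:
        raise ValueError(
            f"spectra of length {X.shape[1]} do not fit a model built for "
            f"{model.config.input_length} points"
        )
    if X.shape[0] == 0:
        raise ValueError("cannot train on an empty dataset")
    if refs.n_agents != model.config.n_outputs:
        raise ValueError("reference set size does not match the model output width")

    dt = np.dtype(model.config.dtype)
    Xc = np.ascontiguousarray(X, dtype=dt)
    R = np.ascontiguousarray(refs.matrix, dtype=dt)
    spacing = refs.grid.spacing
    alpha = config.resolve_alpha(refs)
    model.resolve_input_scale(refs)

    from .nn import Adam

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    if config.checkpoint_path is not None and config.checkpoint_interval > 0:
        # run in chunks, persisting a resumable checkpoint after each
        parts: list[TrainingHistory] = []
        done = 0
        history = None
        while done < config.epochs:
            chunk = min(config.checkpoint_interval, config.epochs - done)
            parts.append(
                _run_epochs(
                    model, Xc, R, spacing, alpha, config, optimizer, rng, chunk,
                    log_every,
                )
            )
            done += chunk
            history = TrainingHistory.concatenate(parts)
            save_checkpoint(
                config.checkpoint_path, model, optimizer, rng, config, history
            )
        if history is None:  # epochs == 0
            history = _run_epochs(
                model, Xc, R, spacing, alpha, config, optimizer, rng, 0, log_every
            )
    else:
        history = _run_epochs(
            model, Xc, R, spacing, alpha, config, optimizer, rng, config.epochs,
            log_every,
        )
        if config.checkpoint_path is not None:
            save_checkpoint(
                config.checkpoint_path, model, optimizer, rng, config, history
            )
    return model, history


def save_checkpoint(
    path,
    model: PinnModel,
    optimizer,
    rng: np.random.Generator,
    config: TrainingConfig,
    history: TrainingHistory,
) -> None:
    """Persist everything needed to continue training bit-exactly."""
    header = json.dumps(
        {
            "version": _CHECKPOINT_VERSION,
            "model_seed": model.seed,
            "model_config": asdict(model.config),
            "input_scale": model.input_scale,
            "training_config": asdict(config),
            "epochs_done": history.epochs_run,
            "rng_state": rng.bit_generator.state,
            "alpha": history.alpha,
            "adam_t": optimizer.t,
        }
    )
    payload = {f"param_{i:03d}": p.value for i, p in enumerate(model.parameters())}
    payload.update({f"adam_m_{i:03d}": m for i, m in enumerate(optimizer.m)})
    payload.update({f"adam_v_{i:03d}": v for i, v in enumerate(optimizer.v)})
    payload.update(
        hist_rec=history.reconstruction,
        hist_reg=history.smoothness,
        hist_tot=history.total,
        hist_sec=history.seconds,
    )
    np.savez(path, _header=np.frombuffer(header.encode(), dtype=np.uint8), **payload)


def resume(
    checkpoint,
    data,
    references: ReferenceSet | None = None,
    config: TrainingConfig | None = None,
    log_every: int | None = None,
) -> tuple[PinnModel, TrainingHistory]:
    """Continue an interrupted run up to ``config.epochs`` total epochs.

    The supplied configuration must match the stored one in every field
    except ``epochs`` (the new total, which may not be smaller than the
    epochs already run) and the checkpoint fields.  With ``config=None`` the
    stored configuration is reused (a no-op if the run already completed).
    The returned history covers the whole run, both halves concatenated.
    """
    try:
        with np.load(checkpoint) as ck:
            header = json.loads(bytes(ck["_header"]).decode())
            if header.get("version") != _CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {header.get('version')}"
                )
            cfg_dict = dict(header["model_config"])
            for key in ("encoder_filters", "pool_sizes"):
                cfg_dict[key] = tuple(cfg_dict[key])
            model = PinnModel(ModelConfig(**cfg_dict), seed=header["model_seed"])
            if header.get("input_scale") is not None:
                model.input_scale = float(header["input_scale"])
            params = model.parameters()
            for i, p in enumerate(params):
                p.value[...] = ck[f"param_{i:03d}"]
            stored = TrainingConfig(**header["training_config"])
            epochs_done = int(header["epochs_done"])
            from .nn import Adam

            optimizer = Adam(params, lr=stored.learning_rate)
            optimizer.t = int(header["adam_t"])
            for i in range(len(params)):
                optimizer.m[i][...] = ck[f"adam_m_{i:03d}"]
                optimizer.v[i][...] = ck[f"adam_v_{i:03d}"]
            rng = np.random.default_rng()
            rng.bit_generator.state = header["rng_state"]
            alpha = float(header["alpha"])
            past = TrainingHistory(
                ck["hist_rec"].copy(),
                ck["hist_reg"].copy(),
                ck["hist_tot"].copy(),
                ck["hist_sec"].copy(),
                alpha,
            )
    except (OSError, KeyError, ValueError, json.JSONDecodeError, zipfile.BadZipFile) as exc:
        raise ValueError(f"cannot read training checkpoint {checkpoint!r}: {exc}") from exc

    if config is None:
        config = stored
    else:
        if asdict(replace(config, epochs=stored.epochs, checkpoint_path=stored.checkpoint_path, checkpoint_interval=stored.checkpoint_interval)) != asdict(stored):
            raise ValueError("resume configuration does not match the checkpoint")
        if config.epochs < epochs_done:
            raise ValueError(
                f"checkpoint already ran {epochs_done} epochs, cannot resume to {config.epochs}"
            )

    X = _extract_spectra(data)
    refs = _extract_references(data, references)
    dt = np.dtype(model.config.dtype)
    Xc = np.ascontiguousarray(X, dtype=dt)
    R = np.ascontiguousarray(refs.matrix, dtype=dt)
    remaining = config.epochs - epochs_done
    extra = _run_epochs(
        model, Xc, R, refs.grid.spacing, alpha, config, optimizer, rng, remaining,
        log_every,
    )
    history = TrainingHistory(
        np.concatenate([past.reconstruction, extra.reconstruction]),
        np.concatenate([past.smoothness, extra.smoothness]),
        np.concatenate([past.total, extra.total]),
        np.concatenate([past.seconds, extra.seconds]),
        alpha,
    )
    if config.checkpoint_path is not None:
        save_checkpoint(config.checkpoint_path, model, optimizer, rng, config, history)
    return model, history
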