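"""Accuracy metrics, the least-squares baseline, and preprocessing utilities.

Prediction quality is summarised the way calibration studies usually do:
per-agent R-squared of target vs predicted concentration, and the mean
relative error |c_p - c| / c in percent over samples whose true
concentration clears a floor (relative error diverges as c -> 0; the floor
defaults to 0.1 on the benchmark's 0-2 range).  Mean absolute error is
reported for all samples.

For a constant background the whole problem has a closed-form solution:
per-spectrum ordinary least squares of the measurement against the
reference spectra plus a constant offset.  :func:`least_squares_constant_background`
implements it as the independent oracle the network is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import ReferenceSet, Spectrum

__all__ = [
    "EvaluationReport",
    "r_squared",
    "mean_relative_error",
    "mean_absolute_error",
    "evaluate_predictions",
    "least_squares_constant_background",
    "cut_wavelengths",
    "average_spectra",
]


def _paired(targets, predictions) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(targets, dtype=float).ravel()
    p = np.asarray(predictions, dtype=float).ravel()
    if t.size != p.size:
        raise ValueError("targets and predictions differ in length")
    return t, p


def r_squared(targets, predictions) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    t, p = _paired(targets, predictions)
    if t.size < 2:
        raise ValueError("R-squared needs at least two samples")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R-squared is undefined for constant targets")
    ss_res = float(np.sum((t - p) ** 2))
    return 1.0 - ss_res / ss_tot


def mean_relative_error(targets, predictions, floor: float = 0.1) -> float:
    """Mean of |p - t| / t over samples with t >= floor, in percent."""
    if floor <= 0:
        raise ValueError("the relative-error floor must be positive")
    t, p = _paired(targets, predictions)
    keep = t >= floor
    if not np.any(keep):
        raise ValueError(f"no targets at or above the floor {floor}")
    return float(np.mean(np.abs(p[keep] - t[keep]) / t[keep]) * 100.0)


def mean_absolute_error(targets, predictions) -> float:
    t, p = _paired(targets, predictions)
    return float(np.mean(np.abs(p - t)))


@dataclass
class EvaluationReport:
    """Per-agent calibration quality on one dataset split."""

    r2: tuple[float, ...]
    relative_error_pct: tuple[float, ...]
    absolute_error: tuple[float, ...]
    n_samples: int
    n_used_relative: tuple[int, ...]
    floor: float
    pairs: np.ndarray = field(repr=False)  # (n_samples, n_agents, 2): target, predicted

    def summary(self) -> str:
        lines = []
        for j in range(len(self.r2)):
            lines.append(
                f"agent {j + 1}: R2={self.r2[j]:.4f}  "
                f"mean relative error={self.relative_error_pct[j]:.3f}% "
                f"(n={self.n_used_relative[j]} with c>={self.floor})  "
                f"mean |error|={self.absolute_error[j]:.4g}"
            )
        return "\n".join(lines)


def evaluate_predictions(
    targets, predictions, floor: float = 0.1
) -> EvaluationReport:
    """Build the per-agent report from (n_samples, n_agents) arrays."""
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    p = np.atleast_2d(np.asarray(predictions, dtype=float))
    if t.shape[0] == 1 and t.shape[0] != p.shape[0]:
        t = t.T
    if p.shape[0] == 1 and t.shape[0] != p.shape[0]:
        p = p.T
    if t.shape != p.shape:
        raise ValueError(f"target shape {t.shape} does not match predictions {p.shape}")
    r2 = tuple(r_squared(t[:, j], p[:, j]) for j in range(t.shape[1]))
    rel = tuple(
        mean_relative_error(t[:, j], p[:, j], floor) for j in range(t.shape[1])
    )
    mae = tuple(mean_absolute_error(t[:, j], p[:, j]) for j in range(t.shape[1]))
    used = tuple(int(np.sum(t[:, j] >= floor)) for j in range(t.shape[1]))
    return EvaluationReport(
        r2=r2,
        relative_error_pct=rel,
        absolute_error=mae,
        n_samples=t.shape[0],
        n_used_relative=used,
        floor=floor,
        pairs=np.stack([t, p], axis=-1),
    )


def least_squares_constant_background(
    spectra: np.ndarray, references: ReferenceSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-spectrum OLS fit of concentrations plus a constant offset.

    Solves min_{c, b0} || I - sum_j c_j I0_j - b0 ||^2 independently for each
    spectrum; optimal whenever the true background is constant (the design
    matrix is the same for all spectra, so one factorisation serves all).
    Returns (concentrations, offsets).
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != references.grid.n_points:
        raise ValueError("spectra and references are on different grids")
    design = np.vstack([references.matrix, np.ones(references.grid.n_points)]).T
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return coef[:-1].T, coef[-1]


def cut_wavelengths(spectrum: Spectrum, lambda_min: float) -> Spectrum:
    """Drop all wavelengths <= lambda_min (a short-wavelength cut-off)."""
    keep = spectrum.grid.values > lambda_min
    if int(keep.sum()) < 2:
        raise ValueError(
            f"cutting at {lambda_min} nm leaves fewer than two grid points"
        )
    if keep.all():
        return Spectrum(spectrum.grid, spectrum.intensities.copy(), dict(spectrum.meta))
    from .spectra import WavelengthGrid

    return Spectrum(
        WavelengthGrid(spectrum.grid.values[keep]),
        spectrum.intensities[keep],
        dict(spectrum.meta),
    )


def average_spectra(spectra) -> Spectrum:
    """Pointwise mean of spectra sharing one grid (noise-reduction averaging)."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average an empty collection of spectra")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise ValueError("spectra are defined on different wavelength grids")
    stack = np.vstack([s.intensities for s in spectra])
    return Spectrum(grid, stack.mean(axis=0))
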