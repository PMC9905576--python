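"""The physics-informed loss: reconstruction + background-smoothness terms.

The network is trained with no concentration labels.  Instead the loss
encodes two physical expectations about a measured spectrum I(lambda):

* reconstruction - the predicted background plus the linear mixture of the
  reference spectra should reproduce the measurement,
  L_rec = sum_lambda (I - sum_j c_p,j I0_j - I_p,b)^2;
* smoothness - the background, being a sum of broad-band effects, should
  carry no sharp spectral features,
  L_reg = sum_lambda (d I_p,b / d lambda)^2.

The total is L_tot = L_rec + alpha * L_reg.  Without the second term the
problem is degenerate (the net could always claim I_p,b = I and c_p = 0);
alpha decides how strongly sharp structure is pushed out of the background
and into the agent term.  The heuristic implemented in
:func:`alpha_heuristic` sets alpha from the reference spectrum alone.  The
ratio

    ell = sum(I0) / sum(|d I0 / d lambda|)

is the characteristic wavelength scale of the reference's features (for a
single emission line it is close to the line width, in nm), and the weight
is taken as its square,

    alpha = ell^2,

the only choice with the nm^2 units that make L_rec and alpha * L_reg
commensurable.  At this magnitude background features sharper than the
reference's own lines cost as much in smoothness as they save in
reconstruction, which is precisely the separation principle the weight is
meant to encode.  Derivatives are discretised as forward differences
divided by the grid step; sums run over wavelengths within one spectrum and
are averaged over a batch, so alpha's meaning does not depend on the batch
size.

A non-linear instrument response can replace the linear mixture: any
callable g(c, lambda) mapping per-agent concentrations to an expected agent
spectrum plugs into :func:`total_loss` through the ``response`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .spectra import ReferenceSet, Spectrum, WavelengthGrid

__all__ = [
    "LossBreakdown",
    "NonlinearResponse",
    "reconstruction_loss",
    "smoothness_loss",
    "total_loss",
    "alpha_heuristic",
]


@dataclass(frozen=True)
class LossBreakdown:
    """The two loss terms, their weight, and the weighted total."""

    reconstruction: float
    smoothness: float
    alpha: float
    total: float


@runtime_checkable
class NonlinearResponse(Protocol):
    """Per-agent response g_j(c_j, lambda) for instruments outside the linear regime.

    Implementations must map a concentration vector to the expected agent
    spectrum on the grid and satisfy g_j(0, lambda) = 0 (no agent, no
    signal).  The linear model corresponds to
    ``lambda c, grid: c @ references.matrix``.
    """

    def __call__(self, concentrations: np.ndarray, grid: WavelengthGrid) -> np.ndarray:
        ...


def _as_batch(x, n_points: int, name: str) -> np.ndarray:
    if isinstance(x, Spectrum):
        x = x.intensities
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != n_points:
        raise ValueError(f"{name} has {arr.shape[1]} points, expected {n_points}")
    return arr


def _agent_term(
    c: np.ndarray,
    references: ReferenceSet,
    response: NonlinearResponse | None,
) -> np.ndarray:
    if response is None:
        return c @ references.matrix
    return np.atleast_2d(np.asarray(response(c, references.grid), dtype=float))


def reconstruction_loss(
    measured,
    concentrations,
    references: ReferenceSet,
    background,
    response: NonlinearResponse | None = None,
) -> float:
    """Squared reconstruction residual, summed over wavelengths, batch-averaged."""
    L = references.grid.n_points
    I = _as_batch(measured, L, "measured")
    B = _as_batch(background, L, "background")
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if c.shape != (I.shape[0], references.n_agents):
        raise ValueError(
            f"concentrations of shape {c.shape} do not match "
            f"{I.shape[0]} samples x {references.n_agents} agents"
        )
    if B.shape[0] != I.shape[0]:
        raise ValueError("measured and background batch sizes differ")
    resid = I - _agent_term(c, references, response) - B
    return float(np.sum(resid * resid, axis=1).mean())


def smoothness_loss(background, spacing: float | None = None, grid: WavelengthGrid | None = None) -> float:
    """Sum of squared forward-difference derivatives of the background.

    ``spacing`` is the uniform grid step in nm; alternatively pass the grid
    (or a Spectrum, whose own grid is used).
    """
    if isinstance(background, Spectrum):
        if grid is None:
            grid = background.grid
        background = background.intensities
    if grid is not None:
        spacing = grid.spacing
    if spacing is None:
        raise ValueError("smoothness_loss needs the grid spacing")
    B = np.atleast_2d(np.asarray(background, dtype=float))
    if B.shape[1] < 2:
        raise ValueError("smoothness loss needs at least two grid points")
    d = np.diff(B, axis=1) / float(spacing)
    return float(np.sum(d * d, axis=1).mean())


def total_loss(
    measured,
    concentrations,
    references: ReferenceSet,
    background,
    alpha: float,
    response: NonlinearResponse | None = None,
) -> LossBreakdown:
    """L_tot = L_rec + alpha * L_reg with the terms reported individually."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    rec = reconstruction_loss(measured, concentrations, references, background, response)
    reg = smoothness_loss(background, spacing=references.grid.spacing)
    return LossBreakdown(
        reconstruction=rec,
        smoothness=reg,
        alpha=float(alpha),
        total=rec + float(alpha) * reg,
    )


def alpha_heuristic(references: ReferenceSet | Spectrum) -> float:
    """Regularisation weight estimated from the reference spectrum alone.

    alpha = ell^2 with ell = sum(I0) / sum(|dI0/dlambda|), the reference's
    characteristic feature scale in nm; derivatives are forward differences
    divided by the grid step.  For several agents the per-agent weights are
    averaged.  The ratio ell is invariant to intensity rescaling and to grid
    translation; alpha quarters when the reference's derivative magnitude
    doubles at fixed sum(I0).
    """
    if isinstance(references, Spectrum):
        references = ReferenceSet(references.grid, references.intensities[None, :])
    step = references.grid.spacing
    values = []
    for row in references.matrix:
        deriv = np.abs(np.diff(row) / step).sum()
        if deriv == 0:
            raise ValueError(
                "alpha heuristic is undefined for a constant reference spectrum"
            )
        ell = row.sum() / deriv
        values.append(ell * ell)
    return float(np.mean(values))


def loss_gradients(
    measured: np.ndarray,
    concentrations: np.ndarray,
    reference_matrix: np.ndarray,
    background: np.ndarray,
    alpha: float,
    spacing: float,
) -> tuple[LossBreakdown, np.ndarray, np.ndarray]:
    """Loss value and its gradients w.r.t. (concentrations, background).

    Internal training helper operating on raw arrays: ``measured`` and
    ``background`` are (batch, n_points), ``concentrations`` is
    (batch, n_agents), ``reference_matrix`` is (n_agents, n_points).  The
    batch-mean reduction matches the public loss functions exactly.
    """
    I = measured
    Bn = I.shape[0]
    resid = I - concentrations @ reference_matrix - background
    rec = float(np.sum(resid * resid, axis=1).mean())
    d = np.diff(background, axis=1) / spacing
    reg = float(np.sum(d * d, axis=1).mean())

    d_conc = (-2.0 / Bn) * (resid @ reference_matrix.T)
    d_bg = (-2.0 / Bn) * resid
    dd = (2.0 * alpha / (Bn * spacing)) * d
    d_bg[:, :-1] -= dd
    d_bg[:, 1:] += dd
    breakdown = LossBreakdown(
        reconstruction=rec,
        smoothness=reg,
        alpha=float(alpha),
        total=rec + float(alpha) * reg,
    )
    return breakdown, d_conc, d_bg
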