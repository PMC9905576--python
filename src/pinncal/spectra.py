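"""Core containers: wavelength grids, spectra, reference sets, labelled samples.

Intensities are kept in arbitrary units (a.u.) exactly as a spectrometer would
report them; nothing here normalises or rescales. A :class:`Spectrum` is one
intensity series on a :class:`WavelengthGrid`; a :class:`ReferenceSet` holds
the unit-concentration emission spectra of the N agents being quantified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "ReferenceSet",
    "LabelledSample",
    "make_wavelength_grid",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """A strictly increasing series of wavelengths in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a wavelength grid needs at least two points")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", values)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def span(self) -> float:
        """Total wavelength span lambda_max - lambda_min (nm)."""
        return float(self.values[-1] - self.values[0])

    @property
    def is_uniform(self) -> bool:
        steps = np.diff(self.values)
        return bool(np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12))

    @property
    def spacing(self) -> float:
        """Grid step in nm; defined only for uniform grids."""
        if not self.is_uniform:
            raise ValueError("spacing is defined only for uniform grids")
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_points

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.shape, self.values.tobytes()))


def make_wavelength_grid(start: float, stop: float, n_points: int) -> WavelengthGrid:
    """Uniform grid from ``start`` to ``stop`` nm inclusive of both endpoints."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    if not stop > start:
        raise ValueError(f"stop ({stop}) must exceed start ({start})")
    return WavelengthGrid(np.linspace(start, stop, n_points))


@dataclass
class Spectrum:
    """One intensity series (a.u.) on a wavelength grid."""

    grid: WavelengthGrid
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.grid.n_points,):
            raise ValueError(
                f"intensity series of length {self.intensities.shape} does not "
                f"match grid of {self.grid.n_points} points"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __add__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return Spectrum(self.grid, self.intensities + other.intensities)

    def __sub__(self, other: "Spectrum") -> "Spectrum":
        self._check_grid(other)
        return Spectrum(self.grid, self.intensities - other.intensities)

    def __mul__(self, scalar: float) -> "Spectrum":
        return Spectrum(self.grid, self.intensities * float(scalar))

    __rmul__ = __mul__

    def _check_grid(self, other: "Spectrum") -> None:
        if self.grid != other.grid:
            raise ValueError("spectra are defined on different wavelength grids")


@dataclass
class ReferenceSet:
    """Unit-concentration reference spectra of the N agents, on one shared grid.

    ``matrix`` has shape (n_agents, n_points); row j is the emission spectrum
    of agent j at concentration 1.
    """

    grid: WavelengthGrid
    matrix: np.ndarray
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.grid.n_points:
            raise ValueError("reference matrix width does not match the grid")
        if not self.names:
            self.names = tuple(f"agent_{j + 1}" for j in range(self.matrix.shape[0]))
        if len(self.names) != self.matrix.shape[0]:
            raise ValueError("one name per reference spectrum is required")

    @property
    def n_agents(self) -> int:
        return int(self.matrix.shape[0])

    def spectrum(self, j: int) -> Spectrum:
        return Spectrum(self.grid, self.matrix[j])

    def mixture(self, concentrations: np.ndarray) -> np.ndarray:
        """Linear mixture sum_j c_j * I0_j(lambda) for one or many samples."""
        c = np.asarray(concentrations, dtype=float)
        return c @ self.matrix


@dataclass
class LabelledSample:
    """A synthetic measurement with its generating truth retained.

    ``components`` maps 'agent', 'background' and 'noise' to the spectra that
    were summed to produce ``measured``; they exist only so tests can verify
    the decomposition and are never consulted during training.
    """

    measured: Spectrum
    concentrations: np.ndarray
    components: dict[str, Spectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.atleast_1d(
            np.asarray(self.concentrations, dtype=float)
        )
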