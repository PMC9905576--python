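"""Synthetic benchmark scenarios N01-N06 for unsupervised spectral calibration.

Each scenario combines a known reference spectrum (one or two agents, each a
sum of two Gaussian emission lines), a background family, and additive white
Gaussian noise:

* N01 - peaked reference, steady constant background (10 a.u.);
* N02 - peaked reference, unsteady constant background (10*eps, eps ~ U[1, 6]);
* N03 - peaked reference, steady shaped background (Gaussian bump at 500 nm);
* N04 - peaked reference, unsteady shaped background (random amplitude and
  position: 50*eps1 * exp(-(lambda - 500 - 200*eps2)^2 / (2*75^2)));
* N05 - broad, non-peaked reference (sigma 45/40 nm) with the N04 background;
* N06 - two agents with peaked references and the N04 background.

A measured spectrum is the exact sum  I = sum_j c_j I0_j + I_back + I_noise
with concentrations drawn uniformly on [0, 2] and i.i.d. zero-mean Gaussian
noise of standard deviation 5 a.u. at every wavelength.  All randomness flows
from a single integer seed, so a dataset is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import (
    LabelledSample,
    ReferenceSet,
    Spectrum,
    WavelengthGrid,
    make_wavelength_grid,
)

__all__ = [
    "PeakParams",
    "ScenarioConfig",
    "SyntheticDataset",
    "SCENARIO_IDS",
    "scenario_peaks",
    "reference_spectrum",
    "reference_set_for",
    "background_sample",
    "noise_sample",
    "synthesize_dataset",
]

#: default wavelength grid: 350-1049 nm, 700 points, 1 nm spacing.  The span
#: covers both emission lines and the full range of background positions, and
#: 700 = 10 * 14 * 5 makes the encoder's pooling chain land on a 7x5 code.
DEFAULT_GRID_START = 350.0
DEFAULT_GRID_STOP = 1049.0
DEFAULT_GRID_POINTS = 700

SCENARIO_IDS = ("N01", "N02", "N03", "N04", "N05", "N06")


@dataclass(frozen=True)
class PeakParams:
    """One Gaussian emission line: I_k * exp(-(lambda - lambda_k)^2 / (2*sigma_k)^2).

    Note the denominator is the *square of twice sigma*, not 2*sigma^2; the
    effective Gaussian standard deviation is therefore sigma_k * sqrt(2).
    """

    amplitude: float  # I_k, a.u.
    center: float  # lambda_k, nm
    width: float  # sigma_k, nm

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("peak amplitude must be non-negative")
        if self.width <= 0:
            raise ValueError("peak width sigma must be positive")


# Reference-spectrum line parameters per scenario (amplitude a.u., centre nm,
# sigma nm).  N05 widens the lines until the reference is no longer peaked.
_PEAKED = (PeakParams(180.0, 656.3, 2.0), PeakParams(60.0, 486.1, 2.0))
_SCENARIO_PEAKS: dict[str, tuple[tuple[PeakParams, PeakParams], ...]] = {
    "N01": (_PEAKED,),
    "N02": (_PEAKED,),
    "N03": (_PEAKED,),
    "N04": (_PEAKED,),
    "N05": ((PeakParams(180.0, 656.3, 45.0), PeakParams(60.0, 486.1, 40.0)),),
    "N06": (
        _PEAKED,
        (PeakParams(240.0, 587.5, 2.0), PeakParams(100.0, 480.0, 2.0)),
    ),
}


def scenario_peaks(scenario: str) -> tuple[tuple[PeakParams, PeakParams], ...]:
    """Per-agent pairs of Gaussian line parameters for a scenario id."""
    try:
        return _SCENARIO_PEAKS[scenario]
    except KeyError:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIO_IDS}"
        ) from None


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one synthetic benchmark draw."""

    scenario: str
    n_samples: int = 1000
    concentration_range: tuple[float, float] = (0.0, 2.0)
    noise_sd: float = 5.0
    seed: int = 0
    grid_start: float = DEFAULT_GRID_START
    grid_stop: float = DEFAULT_GRID_STOP
    grid_points: int = DEFAULT_GRID_POINTS

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_IDS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIO_IDS}"
            )
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")
        lo, hi = self.concentration_range
        if lo < 0 or hi <= lo:
            raise ValueError("concentration range must satisfy 0 <= lo < hi")
        if self.noise_sd < 0:
            raise ValueError("noise standard deviation must be non-negative")

    @property
    def n_agents(self) -> int:
        return len(scenario_peaks(self.scenario))

    def make_grid(self) -> WavelengthGrid:
        return make_wavelength_grid(self.grid_start, self.grid_stop, self.grid_points)


def reference_spectrum(
    peaks: tuple[PeakParams, ...], grid: WavelengthGrid
) -> Spectrum:
    """Evaluate a sum of Gaussian emission lines on a grid.

    I0(lambda) = sum_k I_k exp(-(lambda - lambda_k)^2 / (2 sigma_k)^2).
    """
    lam = grid.values
    out = np.zeros_like(lam)
    for p in peaks:
        out += p.amplitude * np.exp(-((lam - p.center) ** 2) / (2.0 * p.width) ** 2)
    return Spectrum(grid, out)


def reference_set_for(scenario: str, grid: WavelengthGrid) -> ReferenceSet:
    """The scenario's per-agent unit-concentration reference spectra."""
    rows = [reference_spectrum(p, grid).intensities for p in scenario_peaks(scenario)]
    return ReferenceSet(grid, np.vstack(rows))


def _background_matrix(
    scenario: str, grid: WavelengthGrid, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """n background spectra plus the per-sample nuisance draws that made them."""
    lam = grid.values
    if scenario == "N01":
        return np.full((n, lam.size), 10.0), {}
    if scenario == "N02":
        eps = rng.uniform(1.0, 6.0, size=n)
        return 10.0 * eps[:, None] * np.ones_like(lam)[None, :], {"eps": eps}
    if scenario == "N03":
        row = 50.0 * np.exp(-((lam - 500.0) ** 2) / (2.0 * 75.0**2))
        return np.tile(row, (n, 1)), {}
    if scenario in ("N04", "N05", "N06"):
        eps1 = rng.uniform(1.0, 6.0, size=n)
        eps2 = rng.uniform(0.0, 1.0, size=n)
        centers = 500.0 + 200.0 * eps2
        bg = 50.0 * eps1[:, None] * np.exp(
            -((lam[None, :] - centers[:, None]) ** 2) / (2.0 * 75.0**2)
        )
        return bg, {"eps1": eps1, "eps2": eps2}
    raise ValueError(
        f"unknown scenario {scenario!r}; expected one of {SCENARIO_IDS}"
    )


def background_sample(
    config: ScenarioConfig, grid: WavelengthGrid, rng: np.random.Generator
) -> Spectrum:
    """Draw one background spectrum from the scenario's family.

    The nuisance parameters (eps, eps1, eps2) are drawn once per spectrum and
    shared across all wavelengths; they are recorded in ``Spectrum.meta``.
    """
    bg, draws = _background_matrix(config.scenario, grid, 1, rng)
    return Spectrum(grid, bg[0], meta={k: float(v[0]) for k, v in draws.items()})


def noise_sample(
    grid: WavelengthGrid, sd: float, rng: np.random.Generator
) -> Spectrum:
    """I.i.d. zero-mean Gaussian noise, one independent draw per wavelength."""
    if sd < 0:
        raise ValueError("noise standard deviation must be non-negative")
    return Spectrum(grid, rng.normal(0.0, sd, size=grid.n_points) if sd > 0 else np.zeros(grid.n_points))


@dataclass
class SyntheticDataset:
    """A labelled scenario draw: measured spectra plus their generating truth."""

    config: ScenarioConfig
    grid: WavelengthGrid
    references: ReferenceSet
    measured: np.ndarray  # (n_samples, n_points)
    concentrations: np.ndarray  # (n_samples, n_agents)
    agent_component: np.ndarray  # (n_samples, n_points)
    background_component: np.ndarray
    noise_component: np.ndarray
    nuisance_draws: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.measured.shape[0])

    def sample(self, i: int) -> LabelledSample:
        return LabelledSample(
            measured=Spectrum(self.grid, self.measured[i]),
            concentrations=self.concentrations[i],
            components={
                "agent": Spectrum(self.grid, self.agent_component[i]),
                "background": Spectrum(self.grid, self.background_component[i]),
                "noise": Spectrum(self.grid, self.noise_component[i]),
            },
        )

    def samples(self) -> list[LabelledSample]:
        return [self.sample(i) for i in range(self.n_samples)]

    def without_components(self) -> "SyntheticDataset":
        """Measurements-only view: generating components stripped."""
        empty = np.empty((self.n_samples, 0))
        return replace(
            self,
            agent_component=empty,
            background_component=empty,
            noise_component=empty,
            nuisance_draws={},
        )


def synthesize_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Generate a full labelled dataset for one scenario.

    Each measured spectrum is the exact elementwise sum of its stored agent,
    background and noise components; concentrations are uniform on the
    configured range, independently per agent.
    """
    grid = config.make_grid()
    refs = reference_set_for(config.scenario, grid)
    rng = np.random.default_rng(config.seed)

    lo, hi = config.concentration_range
    conc = rng.uniform(lo, hi, size=(config.n_samples, refs.n_agents))
    agent = conc @ refs.matrix
    background, draws = _background_matrix(
        config.scenario, grid, config.n_samples, rng
    )
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=agent.shape)
    else:
        noise = np.zeros_like(agent)
    measured = agent + background + noise
    return SyntheticDataset(
        config=config,
        grid=grid,
        references=refs,
        measured=measured,
        concentrations=conc,
        agent_component=agent,
        background_component=background,
        noise_component=noise,
        nuisance_draws=draws,
    )
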