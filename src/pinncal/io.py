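"""Plain-text IO: spectra, datasets, prediction tables, flat config files.

All formats are delimited UTF-8 text with '.' as the decimal mark:

* a spectrum file is two tab-separated columns (wavelength_nm, intensity)
  with '#'-prefixed comment/header lines;
* a dataset is a directory holding ``samples.tsv`` (sample_id, c_1..c_N,
  then one intensity column per grid point), ``references.tsv``, a
  ``meta.txt`` key-value sidecar, and - unless exported measurements-only -
  the generating components in ``component_*.tsv``;
* predictions and truth tables are TSV with a sample_id column followed by
  one column per agent.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import ReferenceSet, Spectrum, WavelengthGrid
from .synthetic import ScenarioConfig, SyntheticDataset

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "write_dataset",
    "read_dataset",
    "write_predictions",
    "read_predictions",
    "read_concentration_table",
    "read_config_file",
    "write_config_file",
]


def write_spectrum(spectrum: Spectrum, path) -> None:
    """Two-column text export; metadata entries become '# key: value' lines."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# wavelength_nm\tintensity\n")
        for key, value in spectrum.meta.items():
            fh.write(f"# {key}: {value}\n")
        for lam, inten in zip(spectrum.grid.values, spectrum.intensities):
            fh.write(f"{lam:.12g}\t{inten:.12g}\n")


def read_spectrum(path) -> Spectrum:
    """Parse a two-column spectrum file, reporting the line of any bad row."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectrum file not found: {path}")
    wavelengths: list[float] = []
    intensities: list[float] = []
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected two columns, got {len(parts)}"
                )
            try:
                wavelengths.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric value in {line!r}"
                ) from None
    try:
        grid = WavelengthGrid(np.asarray(wavelengths))
    except ValueError as exc:
        raise ValueError(f"{path}: invalid wavelength column: {exc}") from exc
    return Spectrum(grid, np.asarray(intensities), meta)


def _intensity_columns(grid: WavelengthGrid) -> list[str]:
    return [f"I_{lam:.6g}" for lam in grid.values]


def _samples_frame(dataset: SyntheticDataset, matrix: np.ndarray) -> pd.DataFrame:
    frame = pd.DataFrame(matrix, columns=_intensity_columns(dataset.grid))
    frame.insert(0, "sample_id", np.arange(dataset.n_samples))
    return frame


def write_dataset(dataset: SyntheticDataset, out_dir, measurements_only: bool = False) -> Path:
    """Serialise a synthetic dataset to a directory of TSV files + sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cols = _intensity_columns(dataset.grid)

    frame = _samples_frame(dataset, dataset.measured)
    for j in range(dataset.concentrations.shape[1]):
        frame.insert(1 + j, f"c_{j + 1}", dataset.concentrations[:, j])
    frame.to_csv(out / "samples.tsv", sep="\t", index=False, float_format="%.12g")

    refs = pd.DataFrame(dataset.references.matrix, columns=cols)
    refs.insert(0, "agent", list(dataset.references.names))
    refs.to_csv(out / "references.tsv", sep="\t", index=False, float_format="%.12g")

    if not measurements_only and dataset.agent_component.size:
        for name, mat in (
            ("agent", dataset.agent_component),
            ("background", dataset.background_component),
            ("noise", dataset.noise_component),
        ):
            _samples_frame(dataset, mat).to_csv(
                out / f"component_{name}.tsv", sep="\t", index=False, float_format="%.12g"
            )

    cfg = dataset.config
    meta = {
        "scenario": cfg.scenario,
        "seed": cfg.seed,
        "n_samples": cfg.n_samples,
        "noise_sd": cfg.noise_sd,
        "concentration_min": cfg.concentration_range[0],
        "concentration_max": cfg.concentration_range[1],
        "grid_start": cfg.grid_start,
        "grid_stop": cfg.grid_stop,
        "grid_points": cfg.grid_points,
        "measurements_only": measurements_only,
    }
    write_config_file(meta, out / "meta.txt")
    return out


def read_dataset(in_dir) -> SyntheticDataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    src = Path(in_dir)
    meta = read_config_file(src / "meta.txt")
    config = ScenarioConfig(
        scenario=str(meta["scenario"]),
        n_samples=int(meta["n_samples"]),
        concentration_range=(
            float(meta["concentration_min"]),
            float(meta["concentration_max"]),
        ),
        noise_sd=float(meta["noise_sd"]),
        seed=int(meta["seed"]),
        grid_start=float(meta["grid_start"]),
        grid_stop=float(meta["grid_stop"]),
        grid_points=int(meta["grid_points"]),
    )
    grid = config.make_grid()
    frame = pd.read_csv(src / "samples.tsv", sep="\t")
    c_cols = [c for c in frame.columns if c.startswith("c_")]
    i_cols = [c for c in frame.columns if c.startswith("I_")]
    if len(i_cols) != grid.n_points:
        raise ValueError("samples.tsv column count does not match the sidecar grid")
    conc = frame[c_cols].to_numpy(dtype=float)
    measured = frame[i_cols].to_numpy(dtype=float)

    refs_frame = pd.read_csv(src / "references.tsv", sep="\t")
    references = ReferenceSet(
        grid,
        refs_frame[i_cols].to_numpy(dtype=float),
        tuple(refs_frame["agent"].astype(str)),
    )

    def _component(name: str) -> np.ndarray:
        path = src / f"component_{name}.tsv"
        if not path.exists():
            return np.empty((measured.shape[0], 0))
        comp = pd.read_csv(path, sep="\t")
        return comp[i_cols].to_numpy(dtype=float)

    return SyntheticDataset(
        config=config,
        grid=grid,
        references=references,
        measured=measured,
        concentrations=conc,
        agent_component=_component("agent"),
        background_component=_component("background"),
        noise_component=_component("noise"),
    )


def write_predictions(concentrations: np.ndarray, path, sample_ids=None) -> None:
    c = np.atleast_2d(np.asarray(concentrations, dtype=float))
    if sample_ids is None:
        sample_ids = np.arange(c.shape[0])
    frame = pd.DataFrame(
        c, columns=[f"c_p_{j + 1}" for j in range(c.shape[1])]
    )
    frame.insert(0, "sample_id", sample_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_predictions(path) -> tuple[np.ndarray, np.ndarray]:
    frame = pd.read_csv(path, sep="\t")
    cols = [c for c in frame.columns if c != "sample_id"]
    return frame["sample_id"].to_numpy(), frame[cols].to_numpy(dtype=float)


def read_concentration_table(path) -> np.ndarray:
    """Per-agent concentration columns (c_1.., or c_p_1..) from any TSV table."""
    import re

    frame = pd.read_csv(path, sep="\t")
    cols = [c for c in frame.columns if re.fullmatch(r"c_\d+", c)]
    if not cols:
        cols = [c for c in frame.columns if re.fullmatch(r"c_p_\d+", c)]
    if not cols:
        cols = [c for c in frame.columns if c != "sample_id" and not c.startswith("I_")]
    if not cols:
        raise ValueError(f"{path}: no concentration columns found")
    return frame[cols].to_numpy(dtype=float)


def _parse_scalar(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if text.lower() in ("true", "false"):
        return text.lower() == "true"
    return text


def read_config_file(path) -> dict:
    """Flat 'key = value' text file; '#' starts a comment."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"config file not found: {path}")
    out: dict = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            out[key.strip()] = _parse_scalar(value.strip())
    return out


def write_config_file(values: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in values.items():
            fh.write(f"{key} = {value}\n")
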