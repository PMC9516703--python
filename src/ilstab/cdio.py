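"""Reading, validating and normalizing variable-temperature CD melt data.

A melt experiment records ellipticity (millidegrees) on a temperature x
wavelength grid.  This module ingests such grids from delimited text files
(wide or long layout), attaches sample metadata, converts raw ellipticity to
mean residue ellipticity (MRE, deg cm^2 dmol^-1) and extracts
single-wavelength traces -- conventionally at 218 nm, where the beta-sheet
negative band of an antibody sits.
"""

from __future__ import annotations

import hashlib
import io
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, PreconditionError

logger = logging.getLogger(__name__)

__all__ = [
    "SampleMeta",
    "CDSpectrumSeries",
    "MRETrace",
    "read_cd_table",
    "write_cd_table",
    "compute_mre",
    "extract_trace",
    "ionic_strength_from_wt",
]

DEFAULT_PATH_LENGTH_CM = 0.1


@dataclass(frozen=True)
class SampleMeta:
    """Formulation and instrument metadata for one CD sample.

    Parameters
    ----------
    sample_id : str
        Free-text identifier, e.g. ``"IgG4-50wt-fresh"``.
    solvent_label : str
        Human-readable solvent description, e.g. ``"10 wt % [Cho]Cl"``.
    cosolute_wt_percent : float
        Co-solute mass fraction in percent, in [0, 100].
    protein_conc : float
        Protein concentration in mg/mL, strictly positive.
    path_length : float
        Cuvette path length in cm, strictly positive.
    mean_residue_weight : float
        Mean residue weight in g/mol, strictly positive.
    storage_state : {"fresh", "stored"}
        Whether the sample was measured fresh or after storage.
    ph, ionic_strength, zeta_potential, hydrodynamic_diameter : float, optional
        Companion measurements carried as metadata only (pH unitless,
        ionic strength mol/L, zeta potential mV, diameter nm).
    """

    sample_id: str
    solvent_label: str = "water"
    cosolute_wt_percent: float = 0.0
    protein_conc: float = 0.4
    path_length: float = DEFAULT_PATH_LENGTH_CM
    mean_residue_weight: float = 113.0
    storage_state: Literal["fresh", "stored"] = "fresh"
    ph: Optional[float] = None
    ionic_strength: Optional[float] = None
    zeta_potential: Optional[float] = None
    hydrodynamic_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        if self.storage_state not in ("fresh", "stored"):
            raise PreconditionError(
                f"storage_state must be 'fresh' or 'stored', got {self.storage_state!r}"
            )
        if not 0.0 <= self.cosolute_wt_percent <= 100.0:
            raise PreconditionError(
                f"cosolute_wt_percent must lie in [0, 100], got {self.cosolute_wt_percent}"
            )
        for name in ("protein_conc", "path_length", "mean_residue_weight"):
            value = getattr(self, name)
            if not value > 0:
                raise PreconditionError(f"{name} must be strictly positive, got {value}")
        if self.path_length == DEFAULT_PATH_LENGTH_CM:
            logger.debug("path_length at default %.3g cm for %s",
                         DEFAULT_PATH_LENGTH_CM, self.sample_id)


@dataclass
class CDSpectrumSeries:
    """Ellipticity (or MRE) grid over a temperature ramp.

    ``ellipticity`` has shape (n_temperatures, n_wavelengths); the ``units``
    field records whether cells hold raw millidegrees or MRE.
    """

    temperatures: np.ndarray
    wavelengths: np.ndarray
    ellipticity: np.ndarray
    meta: SampleMeta
    units: Literal["mdeg", "mre"] = "mdeg"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.ellipticity.shape != (self.temperatures.size, self.wavelengths.size):
            raise IntegrityError(
                f"ellipticity shape {self.ellipticity.shape} does not match "
                f"{self.temperatures.size} temperatures x {self.wavelengths.size} wavelengths"
            )
        if np.any(np.diff(self.temperatures) <= 0):
            raise IntegrityError("temperatures must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise IntegrityError("wavelengths must be strictly increasing")
        if np.any(~np.isfinite(self.ellipticity)):
            raise IntegrityError("ellipticity grid contains missing or non-finite cells")
        if np.any(self.temperatures < 0) or np.any(self.temperatures > 110):
            raise IntegrityError("temperatures outside the plausible [0, 110] degC range")
        if np.any(self.wavelengths < 150) or np.any(self.wavelengths > 350):
            raise IntegrityError("wavelengths outside the plausible [150, 350] nm range")


@dataclass
class MRETrace:
    """Single-wavelength MRE versus temperature."""

    temperatures: np.ndarray
    mre: np.ndarray
    wavelength: float
    meta: SampleMeta

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.temperatures.size != self.mre.size:
            raise IntegrityError("temperature and MRE vectors differ in length")


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def read_cd_table(
    path: Union[str, Path, io.StringIO],
    meta: SampleMeta,
    layout: Literal["auto", "wide", "long"] = "auto",
) -> CDSpectrumSeries:
    """Read a delimited CD melt table into a validated :class:`CDSpectrumSeries`.

    Two layouts are accepted: *wide* (first column temperature, remaining
    column headers are wavelengths) and *long* (three columns: temperature,
    wavelength, ellipticity).  Comma or tab delimiters, dot decimal
    separator, mandatory header row.  Rows are sorted by temperature and
    columns by wavelength; duplicate (T, lambda) cells or gaps in the grid
    raise :class:`IntegrityError`.
    """
    if isinstance(path, io.StringIO):
        text = path.getvalue()
        source = "<buffer>"
    else:
        source = str(path)
        text = Path(path).read_text()
    lines = text.strip().splitlines()
    if not lines:
        raise FormatError(f"{source}: empty file")
    sep = _sniff_delimiter(lines[0])
    try:
        df = pd.read_csv(io.StringIO(text), sep=sep)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise FormatError(f"{source}: could not parse table ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{source}: expected at least 2 columns, got {df.shape[1]}")

    if layout == "auto":
        header_numeric = all(_is_number(c) for c in df.columns[1:])
        layout = "wide" if (df.shape[1] != 3 or header_numeric) else "long"

    if layout == "wide":
        try:
            wavelengths = np.array([float(c) for c in df.columns[1:]])
        except ValueError as exc:
            raise FormatError(
                f"{source}: wide layout requires numeric wavelength headers "
                f"(first offending header: {_first_non_numeric(df.columns[1:])!r})"
            ) from exc
        temps = _numeric_column(df.iloc[:, 0], source, df.columns[0])
        try:
            values = df.iloc[:, 1:].to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{source}: non-numeric ellipticity cell: {exc}") from exc
        long = pd.DataFrame({
            "temperature": np.repeat(temps, wavelengths.size),
            "wavelength": np.tile(wavelengths, temps.size),
            "ellipticity": values.ravel(),
        })
    else:
        long = df.iloc[:, :3].copy()
        long.columns = ["temperature", "wavelength", "ellipticity"]
        for col in long.columns:
            long[col] = _numeric_column(long[col], source, col)

    if long.duplicated(subset=["temperature", "wavelength"]).any():
        dup = long[long.duplicated(subset=["temperature", "wavelength"])].iloc[0]
        raise IntegrityError(
            f"{source}: duplicate cell at T={dup['temperature']}, wavelength={dup['wavelength']}"
        )
    grid = long.pivot(index="temperature", columns="wavelength", values="ellipticity")
    grid = grid.sort_index(axis=0).sort_index(axis=1)
    if grid.isna().any().any():
        n_missing = int(grid.isna().sum().sum())
        raise IntegrityError(f"{source}: {n_missing} missing cell(s) in the (T, wavelength) grid")
    return CDSpectrumSeries(
        temperatures=grid.index.to_numpy(),
        wavelengths=grid.columns.to_numpy(),
        ellipticity=grid.to_numpy(),
        meta=meta,
    )


def write_cd_table(series: CDSpectrumSeries, path: Union[str, Path],
                   sidecar: bool = True) -> None:
    """Write a series as a wide-layout CSV plus an optional JSON metadata sidecar."""
    df = pd.DataFrame(series.ellipticity,
                      index=pd.Index(series.temperatures, name="temperature"),
                      columns=series.wavelengths)
    df.to_csv(path, float_format="%.10g")
    if sidecar:
        payload = {
            "sample": series.meta.__dict__,
            "units": series.units,
            "sha256": hashlib.sha256(Path(path).read_bytes()).hexdigest(),
        }
        Path(path).with_suffix(".meta.json").write_text(json.dumps(payload, indent=2))


def compute_mre(series: CDSpectrumSeries) -> CDSpectrumSeries:
    """Convert a raw-ellipticity grid to mean residue ellipticity.

    MRE = theta(mdeg) * MRW / (10 * l(cm) * c(mg/mL)), in deg cm^2 dmol^-1.
    The conversion is linear in theta; metadata positivity is validated by
    :class:`SampleMeta` at construction.
    """
    m = series.meta
    if series.units == "mre":
        raise PreconditionError("series is already in MRE units")
    factor = m.mean_residue_weight / (10.0 * m.path_length * m.protein_conc)
    return CDSpectrumSeries(
        temperatures=series.temperatures,
        wavelengths=series.wavelengths,
        ellipticity=series.ellipticity * factor,
        meta=m,
        units="mre",
    )


def extract_trace(series: CDSpectrumSeries, wavelength: float = 218.0) -> MRETrace:
    """Extract the single-wavelength trace nearest the requested wavelength.

    An exact grid match is preferred; otherwise the nearest grid wavelength
    is used (ties break toward the lower wavelength) and a note is logged.
    Requests outside the grid range raise :class:`PreconditionError`.
    """
    wl = series.wavelengths
    if not wl[0] <= wavelength <= wl[-1]:
        raise PreconditionError(
            f"wavelength {wavelength} nm outside grid range [{wl[0]}, {wl[-1]}] nm"
        )
    dist = np.abs(wl - wavelength)
    # stable argmin returns the first (lower-wavelength) index on ties
    idx = int(np.argmin(dist))
    used = float(wl[idx])
    if used != wavelength:
        logger.info("requested %.6g nm not on grid; using nearest %.6g nm", wavelength, used)
    return MRETrace(
        temperatures=series.temperatures,
        mre=series.ellipticity[:, idx],
        wavelength=used,
        meta=series.meta,
    )


def ionic_strength_from_wt(wt_percent: float, molar_mass: float,
                           density: float = 1.00) -> float:
    """Molar concentration of a fully dissociated 1:1 electrolyte from wt %.

    c = 10 * wt% * density / M  (mol/L); for a 1:1 electrolyte the ionic
    strength equals c.  Density defaults to 1.00 g/mL and is overridable
    because concentrated solutions are denser than water.
    """
    if not 0.0 <= wt_percent < 100.0:
        raise PreconditionError(f"wt_percent must lie in [0, 100), got {wt_percent}")
    if molar_mass <= 0 or density <= 0:
        raise PreconditionError("molar_mass and density must be strictly positive")
    return 10.0 * wt_percent * density / molar_mass


def _is_number(token: object) -> bool:
    try:
        float(str(token))
        return True
    except ValueError:
        return False


def _first_non_numeric(tokens) -> Optional[str]:
    for t in tokens:
        if not _is_number(t):
            return str(t)
    return None


def _numeric_column(col: pd.Series, source: str, name: object) -> np.ndarray:
    try:
        return pd.to_numeric(col, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{source}: non-numeric value in column {name!r}: {exc}") from exc
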