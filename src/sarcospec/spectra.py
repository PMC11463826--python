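"""Core domain types and long-format CSV I/O for autofluorescence spectra.

A *spectrum* is one laser acquisition: the spectrometer's wavelength axis
(nm) paired with emission intensities in arbitrary units, labelled with the
acquisition, the source animal and the tissue class (sarcoma or healthy).
All pipeline stages exchange :class:`SpectrumSet` objects, and the only
on-disk format is the long CSV dialect written by :func:`write_spectra_csv`:

    acquisition_id,mouse_id,tissue_class,wavelength_nm,intensity

one row per (acquisition, wavelength), '.' decimals, UTF-8, LF newlines.
Intensities round-trip bit-exactly (shortest ``repr`` of the double).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

CSV_COLUMNS = ["acquisition_id", "mouse_id", "tissue_class", "wavelength_nm", "intensity"]


class TissueClass(str, enum.Enum):
    SARCOMA = "sarcoma"
    HEALTHY = "healthy"

    def __str__(self) -> str:  # serialize as the bare lowercase word
        return self.value


class SpectraFormatError(ValueError):
    """Malformed spectra CSV: wrong columns, bad values, or mixed grids."""


class GridMismatchError(SpectraFormatError):
    """Acquisitions in one set do not share a common wavelength grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavelength grid must be 1-D with at least 2 samples")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: intensities (a.u.) on a wavelength grid plus labels."""

    grid: WavelengthGrid
    intensities: np.ndarray
    acquisition_id: str
    mouse_id: str
    tissue_class: TissueClass

    def __post_init__(self) -> None:
        intensities = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        if intensities.shape != (len(self.grid),):
            raise ValueError("intensities must match the grid length")
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities must be finite")

    def replace_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.grid, intensities, self.acquisition_id, self.mouse_id, self.tissue_class)

    def with_grid(self, grid: WavelengthGrid, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(grid, intensities, self.acquisition_id, self.mouse_id, self.tissue_class)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.grid == other.grid
            and np.array_equal(self.intensities, other.intensities)
            and self.acquisition_id == other.acquisition_id
            and self.mouse_id == other.mouse_id
            and self.tissue_class == other.tissue_class
        )


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one wavelength grid, unique ids."""

    spectra: Sequence[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        if self.spectra:
            grid = self.spectra[0].grid
            for s in self.spectra[1:]:
                if s.grid != grid:
                    raise GridMismatchError(
                        f"acquisition {s.acquisition_id!r} is on a different wavelength grid"
                    )
            ids = [s.acquisition_id for s in self.spectra]
            if len(set(ids)) != len(ids):
                raise SpectraFormatError("acquisition_ids must be unique")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    def __eq__(self, other: object) -> bool:
        # Order-insensitive: the writer canonicalizes row order, so equality
        # compares spectra keyed by acquisition_id.
        if not isinstance(other, SpectrumSet):
            return NotImplemented
        key = lambda s: s.acquisition_id
        return sorted(self.spectra, key=key) == sorted(other.spectra, key=key)

    @property
    def grid(self) -> WavelengthGrid:
        if not self.spectra:
            raise ValueError("empty SpectrumSet has no grid")
        return self.spectra[0].grid

    def intensity_matrix(self) -> np.ndarray:
        """Spectra-by-wavelength matrix (rows follow set order)."""
        return np.vstack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        return np.array([s.tissue_class.value for s in self.spectra])

    def subset(self, indices: Sequence[int]) -> "SpectrumSet":
        return SpectrumSet([self.spectra[i] for i in indices])

    def classes(self) -> dict:
        """Spectra grouped by tissue class, preserving set order."""
        out: dict = {}
        for s in self.spectra:
            out.setdefault(s.tissue_class, []).append(s)
        return out


def write_spectra_csv(spectrum_set: SpectrumSet, path) -> None:
    """Write the long-format CSV; deterministic byte-for-byte.

    Rows are ordered by acquisition_id (lexicographic) then wavelength
    ascending; floats are written as their shortest round-tripping repr.
    """
    if len(spectrum_set) == 0:
        raise ValueError("refusing to write an empty SpectrumSet")
    frames = []
    for s in sorted(spectrum_set, key=lambda s: s.acquisition_id):
        frames.append(
            pd.DataFrame(
                {
                    "acquisition_id": s.acquisition_id,
                    "mouse_id": s.mouse_id,
                    "tissue_class": s.tissue_class.value,
                    "wavelength_nm": s.grid.values,
                    "intensity": s.intensities,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_spectra_csv(path) -> SpectrumSet:
    """Read the long-format CSV back into a :class:`SpectrumSet`.

    Raises :class:`SpectraFormatError` on missing/extra columns or
    non-numeric values and :class:`GridMismatchError` when acquisitions
    disagree on the wavelength grid.
    """
    try:
        # round_trip float parsing: the writer emits shortest-repr doubles
        table = pd.read_csv(
            path,
            dtype={"acquisition_id": str, "mouse_id": str},
            float_precision="round_trip",
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise SpectraFormatError(f"cannot parse spectra CSV: {exc}") from exc
    if list(table.columns) != CSV_COLUMNS:
        raise SpectraFormatError(
            f"expected columns {CSV_COLUMNS}, found {list(table.columns)}"
        )
    for col in ("wavelength_nm", "intensity"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        if numeric.isna().any() and not table[col].isna().any():
            raise SpectraFormatError(f"non-numeric values in column {col!r}")
        if table[col].isna().any():
            raise SpectraFormatError(f"missing values in column {col!r}")
        table[col] = numeric

    spectra = []
    for acq_id, group in table.groupby("acquisition_id", sort=True):
        group = group.sort_values("wavelength_nm", kind="mergesort")
        mouse_ids = group["mouse_id"].unique()
        classes = group["tissue_class"].unique()
        if len(mouse_ids) != 1 or len(classes) != 1:
            raise SpectraFormatError(
                f"acquisition {acq_id!r} has inconsistent mouse_id or tissue_class"
            )
        try:
            tissue = TissueClass(classes[0])
        except ValueError as exc:
            raise SpectraFormatError(f"unknown tissue_class {classes[0]!r}") from exc
        spectra.append(
            Spectrum(
                grid=WavelengthGrid(group["wavelength_nm"].to_numpy()),
                intensities=group["intensity"].to_numpy(),
                acquisition_id=str(acq_id),
                mouse_id=str(mouse_ids[0]),
                tissue_class=tissue,
            )
        )
    return SpectrumSet(spectra)
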