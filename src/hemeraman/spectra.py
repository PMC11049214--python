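"""Spectrum container, metadata, file I/O and regridding.

A recorded Raman/SERS trace is a pair of equal-length arrays — Raman shift in
cm⁻¹ (strictly increasing) and scattered intensity in arbitrary units — plus
an acquisition record saying which protein, variant, redox state and modality
produced it.  Two plain-text dialects are supported: two-column
whitespace-delimited text and CSV with a ``wavenumber_cm-1,intensity`` header.
Metadata travels in a JSON sidecar (same basename, ``.meta.json``); filename
conventions are never parsed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Protein",
    "Redox",
    "Modality",
    "SpectrumMeta",
    "Spectrum",
    "SpectrumFormatError",
    "SpectrumValidationError",
    "read_spectrum",
    "write_spectrum",
    "resample_to_grid",
    "GRID_START",
    "GRID_STOP",
    "GRID_STEP",
]

#: Working grid for the pipeline: covers every marker band used downstream.
GRID_START = 400.0
GRID_STOP = 1800.0
GRID_STEP = 1.0


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed."""


class SpectrumValidationError(ValueError):
    """Spectrum content violates a structural invariant."""


class Protein(str, Enum):
    NGB = "Ngb"
    CYTC = "CytC"
    OTHER = "other"


class Redox(str, Enum):
    OXIDIZED = "oxidized"
    REDUCED = "reduced"
    UNKNOWN = "unknown"


class Modality(str, Enum):
    RRS = "RRS"
    SERS = "SERS"


@dataclass(frozen=True)
class SpectrumMeta:
    """Acquisition metadata for one trace."""

    protein: Protein = Protein.OTHER
    variant: str = "WT"
    redox: Redox = Redox.UNKNOWN
    modality: Modality = Modality.RRS
    replicate: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein", Protein(self.protein))
        object.__setattr__(self, "redox", Redox(self.redox))
        object.__setattr__(self, "modality", Modality(self.modality))
        if not self.variant:
            raise SpectrumValidationError("variant label must be non-empty")
        if self.replicate < 1:
            raise SpectrumValidationError("replicate index must be >= 1")

    def to_dict(self) -> dict:
        return {
            "protein": self.protein.value,
            "variant": self.variant,
            "redox": self.redox.value,
            "modality": self.modality.value,
            "replicate": self.replicate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectrumMeta":
        return cls(**{k: d[k] for k in ("protein", "variant", "redox", "modality", "replicate") if k in d})


@dataclass(frozen=True)
class Spectrum:
    """One trace: wavenumber axis (cm⁻¹), intensities (a.u.), metadata.

    The axis must be strictly increasing with no duplicates and all
    intensities finite.  Constructors that read from disk sort a descending
    axis into ascending order; the constructor itself rejects non-monotone
    input so that in-memory spectra are always well ordered.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SpectrumMeta = field(default_factory=SpectrumMeta)

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", wn)
        object.__setattr__(self, "intensities", inten)
        if wn.ndim != 1 or inten.ndim != 1:
            raise SpectrumValidationError("wavenumbers and intensities must be 1-D")
        if wn.size != inten.size:
            raise SpectrumValidationError(
                f"axis length {wn.size} != intensity length {inten.size}"
            )
        if wn.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(wn)):
            raise SpectrumValidationError("non-finite wavenumber values")
        if not np.all(np.isfinite(inten)):
            raise SpectrumValidationError("non-finite intensity values")
        dif = np.diff(wn)
        if np.any(dif == 0):
            raise SpectrumValidationError("duplicate wavenumber values")
        if np.any(dif < 0):
            raise SpectrumValidationError("wavenumber axis must be strictly increasing")

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def is_uniform(self) -> bool:
        """True when the axis spacing is constant to float tolerance."""
        d = np.diff(self.wavenumbers)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    def scaled(self, factor: float) -> "Spectrum":
        return self.with_intensities(self.intensities * float(factor))

    def covers(self, lo: float, hi: float) -> bool:
        return bool(self.wavenumbers[0] <= lo and self.wavenumbers[-1] >= hi)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix else path.with_name(path.name + ".meta.json")


def _parse_rows(lines: Iterable[str], *, sep: str | None, path: str) -> tuple[np.ndarray, np.ndarray]:
    wn, inten = [], []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(sep) if sep else line.split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            wn.append(float(parts[0]))
            inten.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}: line {lineno}: unparseable row {line!r}") from exc
    return np.asarray(wn), np.asarray(inten)


def read_spectrum(
    path: str | Path,
    dialect: str = "two_column_text",
    meta: SpectrumMeta | None = None,
) -> Spectrum:
    """Read one spectrum from disk.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"two_column_text"`` (whitespace-delimited ν, I rows) or
        ``"csv_with_header"`` (header ``wavenumber_cm-1,intensity``).
    meta
        Explicit metadata.  When omitted, a ``<basename>.meta.json`` sidecar
        is consulted; absent that, neutral defaults are used.

    A descending axis is sorted ascending with intensities co-sorted;
    duplicate wavenumbers raise :class:`SpectrumValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().splitlines()
    if dialect == "two_column_text":
        wn, inten = _parse_rows(text, sep=None, path=str(path))
    elif dialect == "csv_with_header":
        if not text or "wavenumber" not in text[0].lower():
            raise SpectrumFormatError(f"{path}: line 1: missing 'wavenumber_cm-1,intensity' header")
        wn, inten = _parse_rows(text[1:], sep=",", path=str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if wn.size and np.any(np.diff(wn) < 0):
        order = np.argsort(wn, kind="stable")
        wn, inten = wn[order], inten[order]
    if meta is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = SpectrumMeta.from_dict(json.loads(sidecar.read_text()))
        else:
            meta = SpectrumMeta()
    return Spectrum(wn, inten, meta)


def write_spectrum(
    spectrum: Spectrum,
    path: str | Path,
    dialect: str = "two_column_text",
    write_sidecar: bool = True,
) -> Path:
    """Write a spectrum (and its metadata sidecar) to disk; returns the path."""
    path = Path(path)
    lines = []
    if dialect == "two_column_text":
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            lines.append(f"{x:.6f} {y:.10g}")
    elif dialect == "csv_with_header":
        lines.append("wavenumber_cm-1,intensity")
        for x, y in zip(spectrum.wavenumbers, spectrum.intensities):
            lines.append(f"{x:.6f},{y:.10g}")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n")
    if write_sidecar:
        _sidecar_path(path).write_text(json.dumps(spectrum.meta.to_dict(), indent=1))
    return path


def resample_to_grid(spectrum: Spectrum, start: float, stop: float, step: float) -> Spectrum:
    """Linearly interpolate onto a uniform grid ``start..stop`` (inclusive).

    No extrapolation: the requested range must lie inside the recorded axis.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if start >= stop:
        raise ValueError("start must be < stop")
    if start < spectrum.wavenumbers[0] or stop > spectrum.wavenumbers[-1]:
        raise ValueError(
            f"requested range [{start}, {stop}] outside recorded "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}] — no extrapolation"
        )
    n = int(round((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    grid = grid[grid <= stop + 1e-9]
    inten = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return Spectrum(grid, inten, spectrum.meta)
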