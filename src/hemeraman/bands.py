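"""Marker-band tables and band-height quantification.

The porphyrin marker bands used throughout heme Raman work are encoded here
per protein (heme *b* in neuroglobin vs. covalently bound heme *c* in
cytochrome *c*) and redox state.  The ν₄ symmetric pyrrole half-ring mode is
the redox reporter (≈1375/1371 cm⁻¹ oxidized, 1368/1365 cm⁻¹ reduced) and,
being insensitive to out-of-plane distortion, the conformational normalizer.
Band intensity is quantified as the baseline-corrected height at the apex —
the highest genuine local maximum inside the band's search window — not as a
fitted area.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .spectra import Protein, Redox, Spectrum

__all__ = [
    "BandDef",
    "PeakMeasurement",
    "BandLookupError",
    "BandCoverageError",
    "default_band_table",
    "quantify_bands",
    "detect_peaks",
    "load_band_table",
    "dump_band_table",
]


class BandLookupError(KeyError):
    """No band table exists for the requested (protein, redox) condition."""


class BandCoverageError(ValueError):
    """The spectrum does not cover a required band window."""


@dataclass(frozen=True)
class BandDef:
    """One marker band: nominal position, search half-window, assignment."""

    name: str
    nominal: float
    half_window: float = 8.0
    assignment: str = ""

    def __post_init__(self) -> None:
        if not 400.0 <= self.nominal <= 1800.0:
            raise ValueError(f"band {self.name}: nominal {self.nominal} outside 400–1800 cm⁻¹")
        if not 3.0 <= self.half_window <= 15.0:
            raise ValueError(f"band {self.name}: half_window {self.half_window} outside [3, 15]")

    @property
    def window(self) -> tuple[float, float]:
        return (self.nominal - self.half_window, self.nominal + self.half_window)


@dataclass(frozen=True)
class PeakMeasurement:
    """Detected apex for one band: position (cm⁻¹) and corrected height (a.u.).

    ``found`` is True only when a genuine interior local maximum with
    non-negative height exists inside the window; otherwise the in-window
    maximum is reported with ``found = False``.
    """

    band: str
    position: float
    height: float
    found: bool

    @property
    def usable_height(self) -> float:
        # negative window maxima contribute zero to ratios
        return max(self.height, 0.0)


# Search half-windows: 8 cm⁻¹ generally; 5 cm⁻¹ for the adjacent heme-type
# (1306/1313) and ν₄ (1365/1368/1371/1375) marker sets so neighbouring
# conditions cannot cross-capture each other's apex.  The oxidized Cyt c ν₄
# keeps the wide window (1363–1379) to accommodate its 1371–1375 spread.
_BANDS: dict[tuple[Protein, Redox], tuple[BandDef, ...]] = {
    (Protein.NGB, Redox.OXIDIZED): (
        BandDef("allbond_748", 748, 8, "breathing of all porphyrin-ring bonds"),
        BandDef("ch3", 1128, 8, "CH₃ side-radical vibrations"),
        BandDef("pyrrole_asym", 1168, 8, "asymmetric pyrrole half-ring stretch"),
        BandDef("heme_b_1306", 1306, 5, "heme b type marker"),
        BandDef("nu4_ox", 1375, 5, "ν₄ symmetric pyrrole half-ring stretch, ferric"),
        BandDef("methine_1586", 1586, 8, "methine-bridge stretch, planarity-sensitive"),
        BandDef("methine_1638", 1638, 8, "methine-bridge stretch, planarity-sensitive"),
    ),
    (Protein.NGB, Redox.REDUCED): (
        BandDef("allbond_748", 748, 8, "breathing of all porphyrin-ring bonds"),
        BandDef("ch3", 1128, 8, "CH₃ side-radical vibrations"),
        BandDef("pyrrole_asym", 1168, 8, "asymmetric pyrrole half-ring stretch"),
        BandDef("heme_b_1306", 1306, 5, "heme b type marker"),
        BandDef("heme_b_red_1342", 1342, 8, "reduced heme b marker"),
        BandDef("nu4_red", 1368, 5, "ν₄ symmetric pyrrole half-ring stretch, ferrous"),
        BandDef("methine_1586", 1586, 8, "methine-bridge stretch (1638 merges in on reduction)"),
    ),
    (Protein.CYTC, Redox.OXIDIZED): (
        BandDef("allbond_748", 748, 8, "breathing of all porphyrin-ring bonds"),
        BandDef("ch3", 1126, 8, "CH₃ side-radical vibrations"),
        BandDef("pyrrole_asym", 1170, 8, "asymmetric pyrrole half-ring stretch"),
        BandDef("heme_c_1313", 1313, 5, "heme c type marker"),
        BandDef("nu4_ox", 1371, 8, "ν₄ symmetric pyrrole half-ring stretch, ferric"),
        BandDef("methine_1586", 1586, 8, "methine-bridge stretch, planarity-sensitive"),
        BandDef("methine_1638", 1638, 8, "methine-bridge stretch, planarity-sensitive"),
    ),
    (Protein.CYTC, Redox.REDUCED): (
        BandDef("ruffling_570", 570, 8, "heme c mode tracking ruffled (out-of-plane) distortion"),
        BandDef("cs_640", 640, 8, "C–S stretch of the cysteine thioether links"),
        BandDef("allbond_748", 748, 8, "breathing of all porphyrin-ring bonds"),
        BandDef("ch3", 1126, 8, "CH₃ side-radical vibrations"),
        BandDef("pyrrole_asym", 1170, 8, "asymmetric pyrrole half-ring stretch"),
        BandDef("heme_c_1313", 1313, 5, "heme c type marker"),
        BandDef("nu4_red", 1365, 5, "ν₄ symmetric pyrrole half-ring stretch, ferrous"),
        BandDef("methine_1590", 1590, 8, "methine-bridge stretch, planarity-sensitive"),
    ),
}


def default_band_table(protein: Protein | str, redox: Redox | str) -> list[BandDef]:
    """Marker-band table for one (protein, redox) condition.

    Exactly the bands needed for that condition's conformational ratios plus
    its heme-type and redox markers.
    """
    key = (Protein(protein), Redox(redox))
    try:
        return list(_BANDS[key])
    except KeyError:
        raise BandLookupError(
            f"no band table for protein={key[0].value!r}, redox={key[1].value!r}"
        ) from None


def _interior_local_maxima(y: np.ndarray, lo_idx: int, hi_idx: int) -> np.ndarray:
    """Indices in (lo_idx, hi_idx) that are genuine local maxima of y."""
    idx = np.arange(max(lo_idx + 1, 1), min(hi_idx, y.size - 1))
    if idx.size == 0:
        return idx
    left, right = y[idx - 1], y[idx + 1]
    mask = (y[idx] >= left) & (y[idx] >= right) & ((y[idx] > left) | (y[idx] > right))
    return idx[mask]


def quantify_bands(spectrum: Spectrum, table: list[BandDef]) -> list[PeakMeasurement]:
    """Measure apex position and height for every band in ``table``.

    The spectrum must be baseline-corrected and cover every band window.  For
    each band the apex is the highest interior local maximum inside
    ``nominal ± half_window``; when none exists the plain in-window maximum is
    reported with ``found = False``.  Height is the corrected intensity at the
    apex; negative apices are flagged ``found = False``.
    """
    wn, y = spectrum.wavenumbers, spectrum.intensities
    out: list[PeakMeasurement] = []
    for band in table:
        lo, hi = band.window
        if not spectrum.covers(lo, hi):
            raise BandCoverageError(
                f"band {band.name}: window [{lo}, {hi}] cm⁻¹ not covered by spectrum "
                f"[{wn[0]}, {wn[-1]}]"
            )
        lo_idx = int(np.searchsorted(wn, lo, side="left"))
        hi_idx = int(np.searchsorted(wn, hi, side="right")) - 1
        cand = _interior_local_maxima(y, lo_idx, hi_idx)
        if cand.size:
            apex = int(cand[np.argmax(y[cand])])
            found = bool(y[apex] >= 0)
        else:
            window = slice(lo_idx, hi_idx + 1)
            apex = lo_idx + int(np.argmax(y[window]))
            found = False
        out.append(PeakMeasurement(band.name, float(wn[apex]), float(y[apex]), found))
    return out


def detect_peaks(spectrum: Spectrum, min_prominence: float = 0.05) -> list[tuple[float, float]]:
    """All local maxima with prominence ≥ ``min_prominence × max(intensity)``.

    Returns ``(position, height)`` pairs sorted by position; an empty list is
    valid output (e.g. for a monotone ramp or a threshold above every peak).
    """
    y = spectrum.intensities
    top = float(y.max())
    if top <= 0:
        return []
    idx, _ = find_peaks(y, prominence=min_prominence * top)
    return [(float(spectrum.wavenumbers[i]), float(y[i])) for i in idx]


def band_prominences(spectrum: Spectrum, windows: dict[str, tuple[float, float]]) -> dict[str, float]:
    """Topographic prominence of the tallest peak inside each named window.

    Windows with no detected peak are omitted.  Used by the heme-type
    classifier, where the 1306 vs. 1313 cm⁻¹ candidates may ride on each
    other's flanks and raw height alone would mislead.
    """
    wn, y = spectrum.wavenumbers, spectrum.intensities
    idx, _ = find_peaks(y)
    if idx.size == 0:
        return {}
    prom = peak_prominences(y, idx)[0]
    pos = wn[idx]
    out: dict[str, float] = {}
    for name, (lo, hi) in windows.items():
        mask = (pos >= lo) & (pos <= hi)
        if mask.any():
            out[name] = float(prom[mask].max())
    return out


def dump_band_table(table: list[BandDef], path: str | Path) -> Path:
    """Write a band table as JSON (the `bands.custom.json` schema)."""
    path = Path(path)
    payload = [
        {"name": b.name, "nominal": b.nominal, "half_window": b.half_window, "assignment": b.assignment}
        for b in table
    ]
    path.write_text(json.dumps(payload, indent=1, ensure_ascii=False))
    return path


def load_band_table(path: str | Path) -> list[BandDef]:
    """Read a JSON band table written by :func:`dump_band_table`."""
    raw = json.loads(Path(path).read_text())
    return [BandDef(**{k: entry[k] for k in ("name", "nominal", "half_window", "assignment") if k in entry}) for entry in raw]
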