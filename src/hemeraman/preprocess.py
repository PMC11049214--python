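"""Baseline subtraction and total-intensity normalization.

SERS/RRS traces of heme proteins sit on a broad fluorescence-type background.
Before band heights can be read off, that background is estimated with an
asymmetric-least-squares (ALS) Whittaker smoother and subtracted; spectra are
then optionally normalized to unit total intensity so traces from different
acquisitions can be overlaid.  All conformational ratio metrics are invariant
under the normalization step, so its placement cannot change results.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import sparse
from scipy.linalg import solveh_banded

from .spectra import Spectrum

__all__ = ["subtract_baseline", "normalize_total", "als_baseline", "NonUniformGridError"]


class NonUniformGridError(ValueError):
    """Raised when an operation requires a uniform wavenumber grid."""


@lru_cache(maxsize=8)
def _penalty_diagonals(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # D'D for the second-difference operator, as its three upper diagonals
    d = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    dtd = (d.T @ d).todia()
    return dtd.diagonal(0).copy(), dtd.diagonal(1).copy(), dtd.diagonal(2).copy()


def als_baseline(
    y: np.ndarray,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 10,
) -> np.ndarray:
    """Asymmetric-least-squares baseline of a uniformly sampled signal.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + smoothness * sum_i (Δ² z_i)^2``
    where points above the current baseline get weight ``asymmetry`` and
    points below get ``1 - asymmetry``.  Peaks (excursions above the smooth
    trend) are thereby ignored while the slowly varying background is tracked.

    Parameters
    ----------
    y
        Signal values on a uniform grid (length ≥ 16).
    smoothness
        Penalty weight λ on squared second differences; larger → stiffer
        baseline.  1e5 suits fluorescence-type Raman backgrounds at
        1 cm⁻¹ sampling.
    asymmetry
        Weight p given to points above the baseline, 0 < p < 1 (typically
        0.001–0.1).
    max_iter
        Weight-reweighting iterations; converges in a few steps.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 16:
        raise ValueError("baseline estimation needs at least 16 points")
    if not 0.0 < asymmetry < 1.0:
        raise ValueError("asymmetry must lie in (0, 1)")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    d0, d1, d2 = _penalty_diagonals(n)
    ab = np.zeros((3, n))
    ab[0, 2:] = smoothness * d2
    ab[1, 1:] = smoothness * d1
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        ab[2] = smoothness * d0 + w
        z = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > z, asymmetry, 1.0 - asymmetry)
        if np.array_equal(w_new, w):
            break
        w = w_new
    return z


def subtract_baseline(
    spectrum: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 10,
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract the smooth background of one spectrum.

    Returns ``(corrected, baseline)`` with ``corrected = spectrum − baseline``
    pointwise.  Post-correction intensities may dip slightly negative in
    noise; they are deliberately not clipped, keeping the noise model
    unbiased.  Requires a uniform grid (resample first if needed).
    """
    if not spectrum.is_uniform:
        raise NonUniformGridError(
            "baseline subtraction requires a uniform grid; use resample_to_grid first"
        )
    base = als_baseline(spectrum.intensities, smoothness, asymmetry, max_iter)
    return spectrum.with_intensities(spectrum.intensities - base), spectrum.with_intensities(base)


def normalize_total(
    spectrum: Spectrum,
    range_start: float | None = None,
    range_stop: float | None = None,
) -> Spectrum:
    """Scale intensities so their sum over [range_start, range_stop] is 1.

    Defaults to the whole recorded range.  Raises ``ValueError`` when the sum
    over the window is not positive (nothing to normalize to).
    """
    lo = spectrum.wavenumbers[0] if range_start is None else range_start
    hi = spectrum.wavenumbers[-1] if range_stop is None else range_stop
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    total = float(spectrum.intensities[mask].sum())
    if total <= 0:
        raise ValueError(f"intensity sum over [{lo}, {hi}] is {total}; cannot normalize")
    return spectrum.with_intensities(spectrum.intensities / total)
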