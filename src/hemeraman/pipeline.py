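"""End-to-end convenience layer: raw spectrum → tidy metrics table.

Order of operations is fixed: baseline subtraction first, then (optional)
total-intensity normalization, then band quantification and ratio formation.
Ratios are computed per replicate spectrum — never on averaged spectra — and
averaging happens only in the statistics layer.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .bands import BandDef, default_band_table, quantify_bands
from .metrics import ConformationMetrics, compute_metrics
from .preprocess import normalize_total, subtract_baseline
from .spectra import Spectrum

__all__ = ["preprocess_spectrum", "spectrum_metrics", "metrics_table"]


def preprocess_spectrum(
    spectrum: Spectrum,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
    max_iter: int = 10,
    normalize: bool = True,
) -> Spectrum:
    """Baseline-correct (and by default sum-normalize) one spectrum."""
    corrected, _ = subtract_baseline(spectrum, smoothness, asymmetry, max_iter)
    if normalize:
        corrected = normalize_total(corrected)
    return corrected


def spectrum_metrics(
    spectrum: Spectrum,
    table: Sequence[BandDef] | None = None,
    smoothness: float = 1e5,
    asymmetry: float = 0.01,
) -> ConformationMetrics:
    """Full chain for one raw spectrum; band table defaults to its condition's."""
    meta = spectrum.meta
    if table is None:
        table = default_band_table(meta.protein, meta.redox)
    corrected = preprocess_spectrum(spectrum, smoothness, asymmetry)
    measurements = quantify_bands(corrected, list(table))
    return compute_metrics(measurements, meta.protein, meta.redox)


def metrics_table(spectra: Iterable[Spectrum], **kwargs) -> pd.DataFrame:
    """Tidy metrics for a collection of replicate spectra.

    Columns: protein, variant, redox, modality, replicate, metric, value.
    """
    rows = []
    for sp in spectra:
        m = spectrum_metrics(sp, **kwargs)
        for metric, value in m.as_dict().items():
            rows.append(
                {
                    "protein": sp.meta.protein.value,
                    "variant": sp.meta.variant,
                    "redox": sp.meta.redox.value,
                    "modality": sp.meta.modality.value,
                    "replicate": sp.meta.replicate,
                    "metric": metric,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)
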