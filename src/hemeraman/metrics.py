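"""Conformational ratio indices and heme-type / redox classifiers.

Every index is a ratio of baseline-corrected band heights with the ν₄ mode of
the matching redox state as denominator, because its position and intensity do
not respond to out-of-plane heme deformation — it tracks only protein
concentration.  Lower planarity ratios mean a lower probability of the planar
heme conformation; a lower CH₃ ratio means a more rigid protein
microenvironment around the heme; the ruffling index (570/748, reduced heme c
only) tracks the ruffled out-of-plane distortion; the C–S index (640/ν₄)
tracks mobility of the thioether links anchoring heme c.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .bands import BandCoverageError, PeakMeasurement, band_prominences, quantify_bands
from .spectra import Protein, Redox, Spectrum

__all__ = [
    "ConformationMetrics",
    "MetricError",
    "compute_metrics",
    "classify_heme_type",
    "classify_redox",
    "RATIO_DEFINITIONS",
]


class MetricError(ValueError):
    """A ratio could not be formed (bad or missing denominator band)."""


#: numerator / denominator band names per (protein, redox) condition.
RATIO_DEFINITIONS: dict[tuple[Protein, Redox], dict[str, tuple[str, str]]] = {
    (Protein.NGB, Redox.OXIDIZED): {
        "planarity": ("methine_1638", "nu4_ox"),
        "pyrrole_mobility": ("pyrrole_asym", "nu4_ox"),
        "ch3_rigidity": ("ch3", "nu4_ox"),
    },
    (Protein.NGB, Redox.REDUCED): {
        # the 1638 cm⁻¹ methine band merges into 1586 on reduction
        "planarity": ("methine_1586", "nu4_red"),
        "pyrrole_mobility": ("pyrrole_asym", "nu4_red"),
        "ch3_rigidity": ("ch3", "nu4_red"),
    },
    (Protein.CYTC, Redox.OXIDIZED): {
        "planarity": ("methine_1638", "nu4_ox"),
        "pyrrole_mobility": ("pyrrole_asym", "nu4_ox"),
        "ch3_rigidity": ("ch3", "nu4_ox"),
    },
    (Protein.CYTC, Redox.REDUCED): {
        "planarity": ("methine_1590", "nu4_red"),
        "pyrrole_mobility": ("pyrrole_asym", "nu4_red"),
        "ch3_rigidity": ("ch3", "nu4_red"),
        "ruffling": ("ruffling_570", "allbond_748"),
        "cs_mobility": ("cs_640", "nu4_red"),
    },
}


@dataclass(frozen=True)
class ConformationMetrics:
    """The ratio indices for one spectrum.

    ``ruffling`` and ``cs_mobility`` exist only for reduced cytochrome *c*
    (they require the 570/640 cm⁻¹ heme-c modes, silent when oxidized) and are
    ``None`` elsewhere, never zero-filled.
    """

    planarity: float
    pyrrole_mobility: float
    ch3_rigidity: float
    ruffling: float | None = None
    cs_mobility: float | None = None
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        out = {
            "planarity": self.planarity,
            "pyrrole_mobility": self.pyrrole_mobility,
            "ch3_rigidity": self.ch3_rigidity,
        }
        if self.ruffling is not None:
            out["ruffling"] = self.ruffling
        if self.cs_mobility is not None:
            out["cs_mobility"] = self.cs_mobility
        return out


def compute_metrics(
    measurements: list[PeakMeasurement],
    protein: Protein | str,
    redox: Redox | str,
) -> ConformationMetrics:
    """Form the condition-specific ratio indices from band measurements.

    The denominator band (ν₄, or 748 cm⁻¹ for the ruffling index) must be a
    genuinely found peak with positive height; numerators that were not found
    contribute their non-negative in-window maximum, so a vanished band gives
    a (near-)zero ratio rather than an error.
    """
    key = (Protein(protein), Redox(redox))
    if key not in RATIO_DEFINITIONS:
        raise MetricError(f"no ratio definitions for {key[0].value}/{key[1].value}")
    by_name = {m.band: m for m in measurements}
    values: dict[str, float] = {}
    provenance: dict[str, tuple[str, str]] = {}
    for metric, (num_name, den_name) in RATIO_DEFINITIONS[key].items():
        for name in (num_name, den_name):
            if name not in by_name:
                raise BandCoverageError(f"metric {metric}: band {name} missing from measurements")
        num, den = by_name[num_name], by_name[den_name]
        if not den.found or den.height <= 0:
            raise MetricError(
                f"metric {metric}: denominator band {den_name} not found or non-positive "
                f"(height={den.height:.4g}, found={den.found})"
            )
        values[metric] = num.usable_height / den.height
        provenance[metric] = (num_name, den_name)
    return ConformationMetrics(
        planarity=values["planarity"],
        pyrrole_mobility=values["pyrrole_mobility"],
        ch3_rigidity=values["ch3_rigidity"],
        ruffling=values.get("ruffling"),
        cs_mobility=values.get("cs_mobility"),
        provenance=provenance,
    )


def _measurement_lookup(x) -> dict[str, PeakMeasurement] | None:
    if isinstance(x, Spectrum):
        return None
    return {m.band: m for m in x}


def classify_heme_type(x: Spectrum | list[PeakMeasurement]) -> str:
    """Decide heme *b* vs heme *c* from the 1306 / 1313 cm⁻¹ marker region.

    Heme *b* (e.g. neuroglobin) shows the 1306 cm⁻¹ marker; covalently bound
    heme *c* (cytochrome *c*) shows 1313 cm⁻¹ instead.  The two candidate
    windows (1306 ± 5, 1313 ± 4) are compared by apex prominence; a
    prominence ratio within [0.8, 1.25] is too close to call.  A found
    1342 cm⁻¹ band (the reduced heme-*b* marker) adds one vote for heme *b*.
    Returns ``"heme_b"``, ``"heme_c"`` or ``"indeterminate"``.
    """
    windows = {"b": (1301.0, 1311.0), "c": (1309.0, 1317.0), "b_red": (1337.0, 1347.0)}
    by_name = _measurement_lookup(x)
    if by_name is None:
        spectrum: Spectrum = x
        if not spectrum.covers(1290.0, 1325.0):
            raise BandCoverageError("heme-type classification needs coverage of 1290–1325 cm⁻¹")
        prom = band_prominences(spectrum, windows)
        p_b, p_c = prom.get("b"), prom.get("c")
        # the 1342 vote must come from a real band, not a noise ripple:
        # demand a prominence comparable to the heme-type candidates
        p_1342 = prom.get("b_red")
        ref = max((v for v in (p_b, p_c) if v is not None), default=None)
        if p_1342 is None:
            has_1342 = False
        elif ref is not None:
            has_1342 = p_1342 >= 0.2 * ref
        else:
            has_1342 = p_1342 >= 0.05 * float(spectrum.intensities.max())
    else:
        def _height(name):
            m = by_name.get(name)
            return m.usable_height if m is not None and m.found else None

        p_b, p_c = _height("heme_b_1306"), _height("heme_c_1313")
        m1342 = by_name.get("heme_b_red_1342")
        has_1342 = bool(m1342 is not None and m1342.found)

    votes_b = votes_c = 0
    if p_b is not None and p_c is not None:
        ratio = p_b / p_c if p_c > 0 else float("inf")
        if ratio > 1.25:
            votes_b += 1
        elif ratio < 0.8:
            votes_c += 1
    elif p_b is not None:
        votes_b += 1
    elif p_c is not None:
        votes_c += 1
    if has_1342:
        votes_b += 1
    if votes_b > votes_c:
        return "heme_b"
    if votes_c > votes_b:
        return "heme_c"
    return "indeterminate"


def classify_redox(x: Spectrum | list[PeakMeasurement]) -> str:
    """Decide oxidized vs reduced from the ν₄ apex position.

    The ν₄ mode sits near 1375/1371 cm⁻¹ in ferric and shifts to 1368/1365
    cm⁻¹ in ferrous hemes.  The tallest genuine local maximum in 1358–1382
    cm⁻¹ decides: apex ≥ 1370 cm⁻¹ → oxidized, < 1370 → reduced (the boundary
    value itself counts as oxidized); no apex → indeterminate.
    """
    by_name = _measurement_lookup(x)
    if by_name is None:
        spectrum: Spectrum = x
        if not spectrum.covers(1355.0, 1385.0):
            raise BandCoverageError("redox classification needs coverage of 1355–1385 cm⁻¹")
        from .bands import BandDef

        meas = quantify_bands(spectrum, [BandDef("nu4_search", 1370.0, 12.0)])[0]
        if not meas.found:
            return "indeterminate"
        apex = meas.position
    else:
        cands = [m for name, m in by_name.items() if name in ("nu4_ox", "nu4_red") and m.found]
        if not cands:
            return "indeterminate"
        apex = max(cands, key=lambda m: m.height).position
    return "oxidized" if apex >= 1370.0 else "reduced"
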