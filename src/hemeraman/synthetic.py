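"""Synthetic RRS/SERS spectrum generator.

No spectra are deposited with the study this pipeline emulates, so replicate
cohorts are simulated: each spectrum is a sum of pseudo-Voigt marker bands at
the positions of the relevant (protein, redox) band table, a smooth broad
background (quadratic trend plus a decaying short-wavenumber tail, mimicking
fluorescence/Rayleigh residue), and Gaussian noise.  Conformational effects
are encoded as multiplicative factors on the amplitudes of the bands they
govern, while ν₄, the 748 cm⁻¹ breathing mode and the heme-type markers stay
fixed — they are the invariant references.  Ratio metrics computed downstream
therefore map linearly onto the latent multipliers, which is what makes
parameter-recovery testing possible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .bands import default_band_table
from .spectra import GRID_START, GRID_STEP, GRID_STOP, Modality, Protein, Redox, Spectrum, SpectrumMeta

__all__ = [
    "ConformationState",
    "GeneratorConfig",
    "state_to_band_amplitudes",
    "generate_spectrum",
    "generate_cohort",
    "paper_like_deltas",
    "pseudo_voigt",
]

#: which latent multiplier scales which bands
MULTIPLIER_TARGETS: dict[str, frozenset[str]] = {
    "planarity": frozenset({"methine_1586", "methine_1590", "methine_1638"}),
    "pyrrole_mobility": frozenset({"pyrrole_asym"}),
    "rigidity_inverse": frozenset({"ch3"}),
    "ruffling": frozenset({"ruffling_570"}),
    "cs_mobility": frozenset({"cs_640"}),
}

# Relative band heights chosen so simulated traces qualitatively match real
# heme-protein spectra: ν₄ and the 748 cm⁻¹ breathing mode dominate, and the
# 748/CH₃/heme-marker/methine amplitudes rise on reduction.
_OX_COMMON = {
    "allbond_748": 0.80,
    "ch3": 0.45,
    "pyrrole_asym": 0.40,
    "nu4_ox": 1.00,
    "methine_1586": 0.55,
    "methine_1638": 0.45,
}
BASE_AMPLITUDES: dict[tuple[Protein, Redox], dict[str, float]] = {
    (Protein.NGB, Redox.OXIDIZED): {**_OX_COMMON, "heme_b_1306": 0.35},
    (Protein.CYTC, Redox.OXIDIZED): {**_OX_COMMON, "heme_c_1313": 0.35},
    (Protein.NGB, Redox.REDUCED): {
        "allbond_748": 1.20,
        "ch3": 0.65,
        "pyrrole_asym": 0.50,
        "heme_b_1306": 0.55,
        "heme_b_red_1342": 0.70,
        "nu4_red": 1.00,
        "methine_1586": 0.90,
    },
    (Protein.CYTC, Redox.REDUCED): {
        "ruffling_570": 0.30,
        "cs_640": 0.25,
        "allbond_748": 1.20,
        "ch3": 0.65,
        "pyrrole_asym": 0.50,
        "heme_c_1313": 0.55,
        "nu4_red": 1.00,
        "methine_1590": 0.90,
    },
}


@dataclass(frozen=True)
class ConformationState:
    """Latent conformational parameters of one simulated protein variant.

    All multipliers are relative to the wild type (all 1.0) and must lie in
    (0, 3].  ``ruffling`` and ``cs_mobility`` only act on cytochrome-*c*
    reduced spectra, the sole condition whose band table carries the 570 and
    640 cm⁻¹ modes.
    """

    protein: Protein
    redox: Redox
    planarity: float = 1.0
    pyrrole_mobility: float = 1.0
    rigidity_inverse: float = 1.0
    ruffling: float = 1.0
    cs_mobility: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein", Protein(self.protein))
        object.__setattr__(self, "redox", Redox(self.redox))
        for name in MULTIPLIER_TARGETS:
            v = getattr(self, name)
            if not 0.0 < v <= 3.0:
                raise ValueError(f"{name} multiplier {v} outside (0, 3]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Shape, background and noise parameters of the generator.

    ``fwhm`` (cm⁻¹, default 14) and pseudo-Voigt ``mixing`` (Lorentzian
    fraction, default 0.5) apply to every band.  The background is
    ``c0 + c1·t + c2·t² + tail_amp·exp(−t/tail_scale)`` with
    ``t = (ν − start)/(stop − start)``.  ``noise_sigma`` is the per-point
    Gaussian noise SD in the same arbitrary units as the amplitudes;
    0.02 against a ν₄ amplitude of 1.0 gives SNR ≈ 50.
    """

    base_amplitudes: Mapping[str, float] | None = None
    fwhm: float = 14.0
    mixing: float = 0.5
    baseline_quadratic: tuple[float, float, float] = (0.6, 0.4, -0.25)
    baseline_tail: tuple[float, float] = (1.5, 0.18)
    noise_sigma: float = 0.02
    grid_start: float = GRID_START
    grid_stop: float = GRID_STOP
    grid_step: float = GRID_STEP

    def __post_init__(self) -> None:
        if not 6.0 <= self.fwhm <= 30.0:
            raise ValueError(f"fwhm {self.fwhm} outside [6, 30] cm⁻¹")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("pseudo-Voigt mixing must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)

    def baseline(self, wavenumbers: np.ndarray) -> np.ndarray:
        t = (wavenumbers - self.grid_start) / (self.grid_stop - self.grid_start)
        c0, c1, c2 = self.baseline_quadratic
        amp, scale = self.baseline_tail
        return c0 + c1 * t + c2 * t**2 + amp * np.exp(-t / scale)


def pseudo_voigt(x: np.ndarray, center: float, fwhm: float, mixing: float) -> np.ndarray:
    """Height-normalized pseudo-Voigt profile (1 at the apex)."""
    half = fwhm / 2.0
    lorentz = 1.0 / (1.0 + ((x - center) / half) ** 2)
    gauss = np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)
    return mixing * lorentz + (1.0 - mixing) * gauss


def state_to_band_amplitudes(
    state: ConformationState, config: GeneratorConfig | None = None
) -> dict[str, float]:
    """Map a latent state to per-band apex amplitudes.

    Each band's base amplitude is multiplied by the one latent factor that
    governs it; ν₄, 748 cm⁻¹ and the heme-type/redox markers carry no factor.
    """
    config = config or GeneratorConfig()
    base = dict(config.base_amplitudes) if config.base_amplitudes is not None else dict(
        BASE_AMPLITUDES[(state.protein, state.redox)]
    )
    table_names = {b.name for b in default_band_table(state.protein, state.redox)}
    unknown = set(base) - table_names
    if unknown:
        raise ValueError(f"base_amplitudes name bands absent from the condition's table: {sorted(unknown)}")
    missing = table_names - set(base)
    if missing:
        raise ValueError(f"base_amplitudes missing bands: {sorted(missing)}")
    out = {}
    for name, amp in base.items():
        for factor_name, targets in MULTIPLIER_TARGETS.items():
            if name in targets:
                amp = amp * getattr(state, factor_name)
        out[name] = amp
    return out


def _render(
    amplitudes: Mapping[str, float],
    state: ConformationState,
    config: GeneratorConfig,
    rng: np.random.Generator | None,
    meta: SpectrumMeta,
) -> Spectrum:
    grid = config.grid
    table = {b.name: b for b in default_band_table(state.protein, state.redox)}
    y = config.baseline(grid)
    for name, amp in amplitudes.items():
        y = y + amp * pseudo_voigt(grid, table[name].nominal, config.fwhm, config.mixing)
    if rng is not None and config.noise_sigma > 0:
        y = y + rng.normal(0.0, config.noise_sigma, size=grid.size)
    return Spectrum(grid, y, meta)


def _default_meta(state: ConformationState, variant: str, replicate: int) -> SpectrumMeta:
    # oxidized samples were measured by SERS, reduced by ordinary RRS
    modality = Modality.SERS if state.redox == Redox.OXIDIZED else Modality.RRS
    return SpectrumMeta(
        protein=state.protein,
        variant=variant,
        redox=state.redox,
        modality=modality,
        replicate=replicate,
    )


def generate_spectrum(
    state: ConformationState,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    variant: str = "WT",
    replicate: int = 1,
) -> Spectrum:
    """One simulated spectrum: bands + background + noise; seeded, hence
    bit-reproducible."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    amps = state_to_band_amplitudes(state, config)
    return _render(amps, state, config, rng, _default_meta(state, variant, replicate))


def generate_cohort(
    wt_state: ConformationState,
    variant_deltas: Mapping[str, Mapping[str, float]],
    n_replicates: int = 5,
    replicate_jitter: float = 0.05,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    intensity_scale_jitter: float = 0.2,
) -> list[Spectrum]:
    """Replicate cohorts for a set of variants of one (protein, redox) condition.

    ``variant_deltas`` maps variant label → overrides of the latent state
    fields (the wild type is just ``{"WT": {}}``).  Each replicate draws
    independent log-normal per-band amplitude jitter (relative SD
    ``replicate_jitter``), one log-normal whole-spectrum intensity factor
    (relative SD ``intensity_scale_jitter``, emulating acquisition-to-
    acquisition signal variation; it cancels in every ratio), and fresh
    Gaussian noise.  Deterministic for a fixed seed.
    """
    if not variant_deltas:
        raise ValueError("variant_deltas must name at least one variant")
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    sigma_band = np.sqrt(np.log1p(replicate_jitter**2)) if replicate_jitter > 0 else 0.0
    sigma_scale = np.sqrt(np.log1p(intensity_scale_jitter**2)) if intensity_scale_jitter > 0 else 0.0
    spectra: list[Spectrum] = []
    for variant, overrides in variant_deltas.items():
        state = replace(wt_state, **dict(overrides))
        base_amps = state_to_band_amplitudes(state, config)
        for rep in range(1, n_replicates + 1):
            scale = float(np.exp(rng.normal(-0.5 * sigma_scale**2, sigma_scale))) if sigma_scale else 1.0
            amps = {}
            for name, amp in base_amps.items():
                jit = float(np.exp(rng.normal(-0.5 * sigma_band**2, sigma_band))) if sigma_band else 1.0
                amps[name] = amp * jit * scale
            spectra.append(_render(amps, state, config, rng, _default_meta(state, variant, rep)))
    return spectra


#: latent-state overrides reproducing the reported effect DIRECTIONS only;
#: magnitudes are free generator parameters (no numeric ratio values are
#: published for any variant).
_PAPER_LIKE: dict[Protein, dict[str, dict[str, float]]] = {
    Protein.NGB: {
        "WT": {},
        "K95E": {"planarity": 0.72, "rigidity_inverse": 0.70, "pyrrole_mobility": 0.75},
        "K67E": {"planarity": 0.68, "rigidity_inverse": 0.85, "pyrrole_mobility": 0.85},
        "E60K": {"planarity": 0.78, "rigidity_inverse": 0.85, "pyrrole_mobility": 0.85},
        "E87K": {},  # closest to wild type of all substitutions
        "E60K/E87K": {"planarity": 0.60, "rigidity_inverse": 0.80, "pyrrole_mobility": 0.80},
    },
    Protein.CYTC: {
        "WT": {},
        "K72E": {},  # no detectable conformational difference from wild type
        "K25E": {"planarity": 1.20, "pyrrole_mobility": 0.80},
        "K25E/K72E": {"planarity": 1.15, "pyrrole_mobility": 0.80, "ruffling": 0.70, "cs_mobility": 0.70},
    },
}


def paper_like_deltas(protein: Protein | str) -> dict[str, dict[str, float]]:
    """The ``paper_like`` preset: variant → latent-state overrides."""
    return {k: dict(v) for k, v in _PAPER_LIKE[Protein(protein)].items()}
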