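import numpy as np
import pytest

from hemeraman import (
    ConformationState,
    GeneratorConfig,
    Protein,
    Redox,
    Spectrum,
    SpectrumMeta,
)

CONDITIONS = [
    (Protein.NGB, Redox.OXIDIZED),
    (Protein.NGB, Redox.REDUCED),
    (Protein.CYTC, Redox.OXIDIZED),
    (Protein.CYTC, Redox.REDUCED),
]


@pytest.fixture
def grid():
    return 400.0 + np.arange(1401)


@pytest.fixture
def noiseless_config():
    return GeneratorConfig(noise_sigma=0.0)


@pytest.fixture
def flat_config():
    """No background, no noise: spectra are pure band sums."""
    return GeneratorConfig(noise_sigma=0.0, baseline_quadratic=(0.0, 0.0, 0.0), baseline_tail=(0.0, 1.0))


def lorentzian(x, center, amplitude, hwhm):
    return amplitude / (1.0 + ((x - center) / hwhm) ** 2)


@pytest.fixture
def make_spectrum(grid):
    def _make(intensities, **meta):
        return Spectrum(grid, np.asarray(intensities, dtype=float), SpectrumMeta(**meta))

    return _make


def wt_state(protein, redox):
    return ConformationState(protein, redox)
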