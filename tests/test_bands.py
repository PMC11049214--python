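import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hemeraman import BandDef, default_band_table, detect_peaks, quantify_bands
from hemeraman.bands import BandCoverageError, BandLookupError, dump_band_table, load_band_table

from conftest import lorentzian

# nominal marker positions per condition (cm⁻¹)
EXPECTED_TABLES = {
    ("Ngb", "oxidized"): {748, 1128, 1168, 1306, 1375, 1586, 1638},
    ("Ngb", "reduced"): {748, 1128, 1168, 1306, 1342, 1368, 1586},
    ("CytC", "oxidized"): {748, 1126, 1170, 1313, 1371, 1586, 1638},
    ("CytC", "reduced"): {570, 640, 748, 1126, 1170, 1313, 1365, 1590},
}


@pytest.mark.parametrize("protein,redox", list(EXPECTED_TABLES))
def test_default_band_tables_nominals(protein, redox):
    table = default_band_table(protein, redox)
    assert {b.nominal for b in table} == EXPECTED_TABLES[(protein, redox)]
    assert len({b.name for b in table}) == len(table)


def test_nu4_band_names_track_redox():
    assert any(b.name == "nu4_ox" and b.nominal == 1375 for b in default_band_table("Ngb", "oxidized"))
    assert any(b.name == "ruffling_570" and b.nominal == 570 for b in default_band_table("CytC", "reduced"))


def test_unsupported_condition_raises():
    with pytest.raises(BandLookupError):
        default_band_table("other", "unknown")


def test_band_def_validation():
    with pytest.raises(ValueError):
        BandDef("x", 2000.0)
    with pytest.raises(ValueError):
        BandDef("x", 1000.0, half_window=20.0)


def test_ratio_band_windows_disjoint_enough():
    """Bands paired in one ratio never share a fully coincident window."""
    from hemeraman.metrics import RATIO_DEFINITIONS

    for (protein, redox), defs in RATIO_DEFINITIONS.items():
        table = {b.name: b for b in default_band_table(protein, redox)}
        for num, den in defs.values():
            assert table[num].window != table[den].window


class TestQuantify:
    def test_single_lorentzian_height_and_position(self, make_spectrum, grid):
        sp = make_spectrum(lorentzian(grid, 1375.0, 2.0, 6.0))
        table = [b for b in default_band_table("Ngb", "oxidized") if b.name == "nu4_ox"]
        (m,) = quantify_bands(sp, table)
        assert m.found
        assert m.height == pytest.approx(2.0, rel=0.01)
        assert abs(m.position - 1375.0) <= 1.0

    def test_zero_spectrum_nothing_found(self, make_spectrum):
        sp = make_spectrum(np.zeros(1401))
        for m in quantify_bands(sp, default_band_table("Ngb", "oxidized")):
            assert not m.found
            assert m.height == 0.0

    def test_overlapping_lorentzians_match_dense_analytic_oracle(self, make_spectrum, grid):
        """Apex heights of the merged methine doublet agree with brute-force
        evaluation of the summed profile on a 0.01 cm⁻¹ grid."""
        hwhm = 7.5  # width 15 cm⁻¹
        profile = lambda x: lorentzian(x, 1586.0, 1.0, hwhm) + lorentzian(x, 1638.0, 0.5, hwhm)
        sp = make_spectrum(profile(grid))
        table = [b for b in default_band_table("Ngb", "oxidized") if b.name in ("methine_1586", "methine_1638")]
        dense = np.arange(1560.0, 1660.0, 0.01)
        dense_y = profile(dense)
        for m in quantify_bands(sp, table):
            band = next(b for b in table if b.name == m.band)
            lo, hi = band.window
            oracle = dense_y[(dense >= lo) & (dense <= hi)].max()
            assert m.height == pytest.approx(oracle, rel=0.02)

    def test_negative_apex_flagged_not_found(self, make_spectrum, grid):
        sp = make_spectrum(-0.5 * np.ones(1401) + lorentzian(grid, 1375.0, 0.2, 6.0))
        table = [b for b in default_band_table("Ngb", "oxidized") if b.name == "nu4_ox"]
        (m,) = quantify_bands(sp, table)
        assert not m.found
        assert m.usable_height == 0.0

    def test_window_outside_range_names_band(self, grid):
        from hemeraman import Spectrum

        sp = Spectrum(grid[:400], np.zeros(400))  # covers 400–799 only
        with pytest.raises(BandCoverageError, match="ch3"):
            quantify_bands(sp, default_band_table("Ngb", "oxidized"))

    def test_heights_scale_ratios_invariant(self, make_spectrum, grid):
        y = lorentzian(grid, 1375.0, 1.0, 7.0) + lorentzian(grid, 1128.0, 0.4, 7.0)
        table = [b for b in default_band_table("Ngb", "oxidized") if b.name in ("nu4_ox", "ch3")]
        h1 = {m.band: m.height for m in quantify_bands(make_spectrum(y), table)}
        h2 = {m.band: m.height for m in quantify_bands(make_spectrum(13.0 * y), table)}
        assert h2["ch3"] / h2["nu4_ox"] == pytest.approx(h1["ch3"] / h1["nu4_ox"], rel=1e-12)
        assert h2["nu4_ox"] == pytest.approx(13.0 * h1["nu4_ox"], rel=1e-12)


class TestDetectPeaks:
    def test_monotone_ramp_empty(self, make_spectrum):
        assert detect_peaks(make_spectrum(np.linspace(0, 1, 1401))) == []

    def test_three_gaussians_detected_at_centers(self, make_spectrum, grid):
        centers = [600.0, 1000.0, 1500.0]
        y = sum(np.exp(-0.5 * ((grid - c) / 6.0) ** 2) for c in centers)
        peaks = detect_peaks(make_spectrum(y), min_prominence=0.1)
        assert len(peaks) == 3
        for (pos, _), c in zip(peaks, centers):
            assert abs(pos - c) <= 1.0

    def test_threshold_above_tallest_gives_empty(self, make_spectrum, grid):
        y = np.exp(-0.5 * ((grid - 1000.0) / 6.0) ** 2)
        assert detect_peaks(make_spectrum(y), min_prominence=1.5) == []


def test_band_table_json_round_trip(tmp_path):
    table = default_band_table("CytC", "reduced")
    path = dump_band_table(table, tmp_path / "bands.custom.json")
    back = load_band_table(path)
    assert back == table


@settings(max_examples=20, deadline=None)
@given(
    amp=st.floats(min_value=0.05, max_value=5.0),
    center=st.floats(min_value=1370.5, max_value=1379.5),
)
def test_apex_within_window_of_nominal(amp, center):
    """Any in-window peak is located within half_window of the nominal."""
    grid = 400.0 + np.arange(1401)
    from hemeraman import Spectrum

    sp = Spectrum(grid, lorentzian(grid, center, amp, 6.0))
    band = BandDef("nu4_ox", 1375.0, 5.0)
    (m,) = quantify_bands(sp, [band])
    if m.found:
        assert abs(m.position - band.nominal) <= band.half_window
        assert m.height >= 0
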