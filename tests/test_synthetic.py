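import numpy as np
import pytest

from hemeraman import (
    ConformationState,
    GeneratorConfig,
    Protein,
    Redox,
    classify_heme_type,
    classify_redox,
    default_band_table,
    generate_cohort,
    generate_spectrum,
    paper_like_deltas,
    preprocess_spectrum,
    quantify_bands,
    state_to_band_amplitudes,
    spectrum_metrics,
)
from hemeraman.metrics import RATIO_DEFINITIONS
from hemeraman.synthetic import BASE_AMPLITUDES

from conftest import CONDITIONS


class TestStateToAmplitudes:
    def test_wild_type_identity(self):
        st = ConformationState(Protein.NGB, Redox.OXIDIZED)
        assert state_to_band_amplitudes(st) == BASE_AMPLITUDES[(Protein.NGB, Redox.OXIDIZED)]

    def test_planarity_scales_methine_only(self):
        st = ConformationState(Protein.NGB, Redox.OXIDIZED, planarity=0.6)
        amps = state_to_band_amplitudes(st)
        base = BASE_AMPLITUDES[(Protein.NGB, Redox.OXIDIZED)]
        assert amps["methine_1638"] == pytest.approx(0.6 * base["methine_1638"])
        assert amps["methine_1586"] == pytest.approx(0.6 * base["methine_1586"])
        assert amps["nu4_ox"] == base["nu4_ox"]
        assert amps["allbond_748"] == base["allbond_748"]

    def test_rigidity_scales_only_ch3_field_by_field(self):
        st = ConformationState(Protein.CYTC, Redox.REDUCED, rigidity_inverse=0.7)
        amps = state_to_band_amplitudes(st)
        base = BASE_AMPLITUDES[(Protein.CYTC, Redox.REDUCED)]
        for name, value in amps.items():
            expected = 0.7 * base[name] if name == "ch3" else base[name]
            assert value == pytest.approx(expected), name

    def test_unknown_band_in_config_rejected(self):
        cfg = GeneratorConfig(base_amplitudes={"not_a_band": 1.0})
        with pytest.raises(ValueError, match="not_a_band"):
            state_to_band_amplitudes(ConformationState(Protein.NGB, Redox.OXIDIZED), cfg)

    def test_multiplier_bounds_enforced(self):
        with pytest.raises(ValueError):
            ConformationState(Protein.NGB, Redox.OXIDIZED, planarity=0.0)
        with pytest.raises(ValueError):
            ConformationState(Protein.NGB, Redox.OXIDIZED, ruffling=3.5)


class TestGenerateSpectrum:
    def test_zero_amplitudes_give_pure_baseline(self):
        names = {b.name for b in default_band_table(Protein.NGB, Redox.OXIDIZED)}
        cfg = GeneratorConfig(noise_sigma=0.0, base_amplitudes={n: 0.0 for n in names})
        sp = generate_spectrum(ConformationState(Protein.NGB, Redox.OXIDIZED), cfg, seed=0)
        assert np.allclose(sp.intensities, cfg.baseline(sp.wavenumbers))

    @pytest.mark.parametrize("protein,redox", CONDITIONS)
    def test_noiseless_apexes_at_nominal_positions(self, protein, redox, noiseless_config):
        sp = generate_spectrum(ConformationState(protein, redox), noiseless_config, seed=0)
        corrected = preprocess_spectrum(sp, normalize=False)
        for m in quantify_bands(corrected, default_band_table(protein, redox)):
            table = {b.name: b for b in default_band_table(protein, redox)}
            assert abs(m.position - table[m.band].nominal) <= 1.0

    def test_same_seed_bit_identical(self):
        st = ConformationState(Protein.CYTC, Redox.REDUCED)
        a = generate_spectrum(st, seed=42)
        b = generate_spectrum(st, seed=42)
        assert np.array_equal(a.intensities, b.intensities)

    def test_meta_populated_from_state(self):
        sp = generate_spectrum(
            ConformationState(Protein.CYTC, Redox.OXIDIZED), seed=0, variant="K25E", replicate=4
        )
        assert sp.meta.protein == Protein.CYTC
        assert sp.meta.redox == Redox.OXIDIZED
        assert sp.meta.variant == "K25E"
        assert sp.meta.replicate == 4
        assert sp.meta.modality.value == "SERS"  # oxidized samples are SERS acquisitions


class TestGenerateCohort:
    def test_variant_and_replicate_counts(self):
        st = ConformationState(Protein.NGB, Redox.REDUCED)
        spectra = generate_cohort(st, paper_like_deltas(Protein.NGB), n_replicates=5, seed=1)
        assert len(spectra) == 30  # 6 variants × 5
        variants = {s.meta.variant for s in spectra}
        assert variants == set(paper_like_deltas(Protein.NGB))

    def test_no_jitter_no_noise_gives_identical_replicates(self):
        st = ConformationState(Protein.NGB, Redox.OXIDIZED)
        cfg = GeneratorConfig(noise_sigma=0.0)
        spectra = generate_cohort(
            st, {"WT": {}}, n_replicates=3, replicate_jitter=0.0, intensity_scale_jitter=0.0,
            seed=0, config=cfg,
        )
        assert np.array_equal(spectra[0].intensities, spectra[1].intensities)
        assert np.array_equal(spectra[0].intensities, spectra[2].intensities)

    def test_deterministic_under_seed(self):
        st = ConformationState(Protein.CYTC, Redox.REDUCED)
        a = generate_cohort(st, paper_like_deltas(Protein.CYTC), seed=9)
        b = generate_cohort(st, paper_like_deltas(Protein.CYTC), seed=9)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.intensities, s2.intensities)

    def test_empty_variant_map_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(ConformationState(Protein.NGB, Redox.OXIDIZED), {}, seed=0)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(ConformationState(Protein.NGB, Redox.OXIDIZED), {"WT": {}}, n_replicates=1, seed=0)


class TestEmulatedSignatures:
    """The generated spectra reproduce the qualitative redox / heme-type
    signatures that the classifiers rely on."""

    def test_nu4_position_shifts_on_reduction(self, noiseless_config):
        def nu4_pos(protein, redox, band):
            sp = generate_spectrum(ConformationState(protein, redox), noiseless_config, seed=0)
            corrected = preprocess_spectrum(sp, normalize=False)
            table = [b for b in default_band_table(protein, redox) if b.name == band]
            return quantify_bands(corrected, table)[0].position

        assert nu4_pos(Protein.NGB, Redox.OXIDIZED, "nu4_ox") > nu4_pos(Protein.NGB, Redox.REDUCED, "nu4_red")
        assert nu4_pos(Protein.CYTC, Redox.OXIDIZED, "nu4_ox") > nu4_pos(Protein.CYTC, Redox.REDUCED, "nu4_red")

    def test_1342_marker_only_in_reduced_heme_b(self):
        assert "heme_b_red_1342" in BASE_AMPLITUDES[(Protein.NGB, Redox.REDUCED)]
        for key in [(Protein.NGB, Redox.OXIDIZED), (Protein.CYTC, Redox.OXIDIZED), (Protein.CYTC, Redox.REDUCED)]:
            assert "heme_b_red_1342" not in BASE_AMPLITUDES[key]

    def test_748_ch3_methine_amplitudes_rise_on_reduction(self):
        for protein in (Protein.NGB, Protein.CYTC):
            ox = BASE_AMPLITUDES[(protein, Redox.OXIDIZED)]
            red = BASE_AMPLITUDES[(protein, Redox.REDUCED)]
            assert red["allbond_748"] > ox["allbond_748"]
            assert red["ch3"] > ox["ch3"]
            methine_red = red.get("methine_1586", red.get("methine_1590"))
            assert methine_red > ox["methine_1586"]

    def test_classifiers_recover_condition_with_noise(self):
        for protein, redox in CONDITIONS:
            sp = generate_spectrum(ConformationState(protein, redox), seed=5)
            corrected = preprocess_spectrum(sp, normalize=False)
            expected_type = "heme_b" if protein == Protein.NGB else "heme_c"
            assert classify_heme_type(corrected) == expected_type
            assert classify_redox(corrected) == redox.value


def test_end_to_end_ratios_match_amplitude_ratios(noiseless_config):
    """On noiseless spectra every computed ratio equals the generating
    amplitude ratio within 5% (residual bounded by band overlap)."""
    for protein, redox in CONDITIONS:
        amps = BASE_AMPLITUDES[(protein, redox)]
        m = spectrum_metrics(generate_spectrum(ConformationState(protein, redox), noiseless_config, seed=0))
        for metric, value in m.as_dict().items():
            num, den = RATIO_DEFINITIONS[(protein, redox)][metric]
            assert value == pytest.approx(amps[num] / amps[den], rel=0.05), (protein, redox, metric)
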