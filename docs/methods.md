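# Methods

## The measurement model

A heme-protein Raman/SERS trace is modelled as

    I(ν) = Σ_b A_b · pV(ν; ν_b, Γ, η) + B(ν) + ε(ν)

where the sum runs over the marker bands of one (protein, redox) condition,
`pV` is a height-normalized pseudo-Voigt profile (Lorentzian fraction η,
FWHM Γ), `B` is a smooth broad background, and ε is white Gaussian noise.
The analysis chain inverts this model only as far as the science needs:
estimate and remove `B`, read each band's apex height `Â_b`, and form
ratios `Â_num / Â_ν₄`.  No profile fitting or deconvolution is performed —
band "intensity" is the baseline-corrected height at the apex, matching the
I_x notation of ratio analyses in this field, and the merged reduced-state
methine region is deliberately treated as a single 1586/1590 band rather
than unmixed.

## Band tables

Each (protein, redox) condition carries exactly the bands its ratios need
plus the heme-type and redox markers: for neuroglobin (heme *b*) 748, 1128,
1168, 1306 cm⁻¹, ν₄ at 1375 (ox) or 1368 (red), 1586 and — oxidized only —
1638 cm⁻¹, plus 1342 cm⁻¹ in the reduced state; for cytochrome *c*
(heme *c*) 748, 1126, 1170, 1313 cm⁻¹, ν₄ at 1371 (ox) or 1365 (red), 1586/
1590 and 1638 cm⁻¹, plus 570 and 640 cm⁻¹ in the reduced state.  Search
windows are ±8 cm⁻¹ generally and ±5 cm⁻¹ for the adjacent heme-type
(1306/1313) and ν₄ (1365–1375) marker sets, the nearest distinct neighbours
being ~7 cm⁻¹ apart.  The oxidized Cyt *c* ν₄ keeps the wide ±8 cm⁻¹ window
(1363–1379): reported apex positions for this band vary between 1371 and
1375 cm⁻¹, and the wide window accepts either.

## Baseline subtraction

Background removal uses the asymmetric-least-squares Whittaker smoother:
minimize Σ w_i (y_i − z_i)² + λ Σ (Δ²z_i)², with w = p above the current
baseline and 1 − p below, iterated to a fixed point (banded Cholesky solve,
O(n) per iteration).  Defaults λ = 1e5, p = 0.01, 10 iterations at 1 cm⁻¹
sampling.  Numerical behaviour worth knowing:

* On a peak-free quadratic background the residual after subtraction is
  < 0.2% of the background range.  A steep exponential flank is followed
  less well, but the error is confined to the outer ~10 grid points at the
  low-wavenumber edge, outside every band window.
* Each pass erodes a small width-dependent fraction of a peak: re-applying
  the smoother to an already-corrected spectrum changes a FWHM-8 cm⁻¹ band
  by < 1% of its amplitude and a FWHM-14 cm⁻¹ band by ~1.5–2%.  Ratios are
  far less affected because numerator and denominator erode similarly.
* Post-correction intensities are not clipped at zero; clipping would bias
  the noise floor and hence small-band ratios upward.

The working grid is 400–1800 cm⁻¹ at 1 cm⁻¹ (covers every band used;
spectral resolution of the emulated instrument is not published, so 1 cm⁻¹
is an assumption).  Operations that need a uniform grid refuse non-uniform
input and point to `resample_to_grid` (linear interpolation, no
extrapolation).

## Normalization and invariance

Spectra may be normalized so their intensity sum over a range equals 1
(useful for overlay figures).  Every ratio index is exactly invariant under
any positive global rescaling, hence under this normalization; the property
is enforced by tests, which is why the pipeline can place normalization
anywhere after baseline subtraction without affecting results.

## Band quantification and classifiers

The apex of a band is the highest *interior* local maximum inside its
window; if none exists the plain window maximum is reported flagged
`found = False`, and negative apices are likewise flagged (their height
enters ratios as 0).  The heme-type classifier compares topographic
prominences of the 1306 ± 5 vs 1313 ± 4 cm⁻¹ candidates (ratio in
[0.8, 1.25] → indeterminate) with one extra heme-*b* vote from a genuine
1342 cm⁻¹ band; a prominence below 20% of the candidate reference is
treated as noise rather than a band, which keeps the vote from flipping on
SNR-50 heme-*c* spectra.  The redox classifier thresholds the ν₄ apex
position at 1370 cm⁻¹ (≥ 1370 → oxidized; the boundary value counts as
oxidized by convention).

## Statistics

Group comparison uses the two-sided Mann–Whitney U test.  For tie-free
pooled samples with n_x + n_y ≤ 16 the null distribution of U is built by
full enumeration of all C(n_x+n_y, n_x) rank assignments and
p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1 — at n = 5 vs 5 the attainable
levels are multiples of 2/252 ≈ 0.0079, so the test is conservative
(empirical type-I error ≈ 0.03–0.04 at nominal 0.05).  Larger or tied
samples fall back to the normal approximation with tie and continuity
corrections; fully degenerate data give p = 1.  "Error of the mean" is the
SEM (sample SD / √n, undefined at n = 1).  No multiplicity correction is
applied by default, matching the per-comparison annotation scheme
(#/## vs reference, */** pairwise); Holm step-down within each metric
family is available behind a flag.  Ratios are always computed per
replicate spectrum, never on averaged spectra.

## Synthetic cohorts

The generator's defaults define the simulated study conditions: n = 5
replicates per variant, pseudo-Voigt bands with FWHM 14 cm⁻¹ and mixing
0.5, noise SD 0.02 against a ν₄ amplitude of 1.0 (SNR ≈ 50), and a
background of comparable magnitude to the bands (quadratic trend plus an
exponential tail emulating fluorescence/Rayleigh residue).  Base amplitudes
make ν₄ and 748 cm⁻¹ dominant and raise the 748/CH₃/heme-marker/methine
amplitudes on reduction, reproducing the qualitative redox signature real
spectra show.  Replicates draw (i) per-band log-normal amplitude jitter,
relative SD 5%, giving the ~7% replicate CV of the ratio indices, and
(ii) one whole-spectrum log-normal intensity factor (relative SD 20%)
emulating acquisition-to-acquisition signal variation, which cancels in
every ratio.

Conformational effects are multiplicative on the amplitudes of the bands
they govern (methine bands for planarity, 1168/1170 for pyrrole mobility,
1128/1126 for microenvironment rigidity, 570 for ruffling, 640 for C–S
mobility); ν₄, 748 cm⁻¹ and the heme-type markers carry no multiplier, so
they stay valid normalizers and the computed ratios map linearly onto the
latent multipliers.  The `paper_like` preset encodes only reported effect
*directions* — no numeric ratio values are published for any variant, so the
magnitudes are this package's own choice, fixed once by a small design-stage
power analysis: effects that the emulated study reports as clearly
significant at n = 5 must be detectable by an exact test whose smallest
two-sided p is 2/252, which at a 7% replicate CV requires planarity
multipliers ≲ 0.8.  The preset uses E60K/E87K 0.60 (strongest), K67E 0.68,
K95E 0.72, E60K 0.78, E87K ≈ wild type for neuroglobin, and for
cytochrome *c* K72E ≡ wild type, K25E planarity 1.20 with pyrrole 0.80, and
K25E/K72E planarity 1.15 with pyrrole/ruffling/C–S decreases.

What the generator does *not* emulate: SERS enhancement physics and its
site-to-site heterogeneity, instrument response and wavelength-dependent
sensitivity, cosmic-ray spikes, band-shape changes (only amplitudes carry
conformational signal; real distortions also shift and broaden bands), and
any absolute intensity scale.  Passing tests therefore demonstrate that the
analysis chain is correct and well-conditioned under realistic band
structure, background and noise — not that it reproduces any measured
ratio value.

## Validation experiments and problem sizes

The validation layer (and the reproduction script `scripts/acceptance.py`)
uses: n = 5 replicates per variant throughout; 20 cohorts per level for the
planarity-recovery curve (multipliers 0.5/0.75/1.0); 200 simulated cohorts
for the direction-of-effect flag rates (four configured neuroglobin
decreases plus the no-effect K72E control, flagged at p < 0.05 with the
correct sign); and 2000 null simulations for the empirical type-I error.
These sizes give Monte-Carlo standard errors of ~1.5% on flag rates and
~0.4% on the type-I error while keeping the whole script under a minute on
one core.

## Known limitations

* Apex heights are read off a 1 cm⁻¹ grid without sub-grid interpolation;
  an off-grid apex of a 14 cm⁻¹-wide band biases the height by < 0.5%.
* Overlapping neighbours contribute tails to each other's apex (≤ ~2% at
  the default band spacing and width); the end-to-end ratio error on
  noiseless spectra stays below 5%, dominated by this overlap plus baseline
  erosion.
* The baseline model and its parameters are an explicit, reproducible
  choice; analyses of measured spectra whose original background treatment
  differed may shift absolute ratio values (though not their invariances).
* The exact test's conservatism at n = 5 means true effect rates near the
  detection threshold are under-flagged; this is a property of the
  statistic, not of the implementation.
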