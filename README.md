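# hemeraman

Quantitative analysis of heme-protein conformation from resonance Raman
(RRS) and surface-enhanced Raman (SERS) spectra.

Charged-residue substitutions on the surfaces of neuroglobin (Ngb, heme *b*)
and cytochrome *c* (Cyt *c*, heme *c*) can distort the heme group and thereby
alter electron transfer between the two proteins.  Raman marker bands report
that distortion: the methine-bridge stretches (≈1586/1590 and 1638 cm⁻¹)
lose intensity when the heme leaves its planar conformation, the CH₃
side-radical band (1128/1126 cm⁻¹) reports the rigidity of the protein
microenvironment, and in reduced heme *c* the 570 cm⁻¹ band tracks the
ruffled distortion while 640 cm⁻¹ tracks C–S thioether mobility.  The ν₄
symmetric pyrrole half-ring mode (1375/1371 cm⁻¹ ferric → 1368/1365 cm⁻¹
ferrous) is insensitive to out-of-plane deformation and serves as the
normalizer, so each conformational index is a band-height ratio such as

    planarity(ox Ngb)   = I₁₆₃₈ / I₁₃₇₅     planarity(red Ngb)  = I₁₅₈₆ / I₁₃₆₈
    planarity(ox Cyt c) = I₁₆₃₈ / I₁₃₇₁     planarity(red Cyt c)= I₁₅₉₀ / I₁₃₆₅
    pyrrole mobility    = I₁₁₆₈(₁₁₇₀) / ν₄  CH₃ index           = I₁₁₂₈(₁₁₂₆) / ν₄
    ruffling (red c)    = I₅₇₀ / I₇₄₈       C–S mobility (red c)= I₆₄₀ / I₁₃₆₅

The package implements the full chain — two-column/CSV spectrum I/O,
asymmetric-least-squares (Whittaker) baseline subtraction, total-intensity
normalization, apex-height band quantification, ratio indices, heme-type and
redox classifiers, and exact Mann–Whitney comparisons of n = 5 replicate
groups with the #/##/*/** annotation scheme — plus a seeded pseudo-Voigt
spectrum generator that emulates the measured cohorts, so every stage is
testable without measured data.  It is written for spectroscopists doing
band-ratio conformational analysis of heme proteins and for anyone needing a
reproducible reference implementation of that workflow.

## Worked example

```python
from hemeraman import (ConformationState, Protein, Redox, generate_cohort,
                       metrics_table, compare_all, summarize, paper_like_deltas)

wt = ConformationState(Protein.NGB, Redox.REDUCED)
spectra = generate_cohort(wt, paper_like_deltas(Protein.NGB), n_replicates=5, seed=7)
tab = metrics_table(spectra)                       # tidy per-replicate ratios
print(summarize(tab[tab.metric == "planarity"]))
for r in compare_all(tab, reference="WT"):
    if r.metric == "planarity" and r.vs_reference:
        print(r.group_a, round(r.u_statistic, 1), round(r.p_value, 4), r.marker)
```

Output:

```
     variant     metric      mean       sem  n
0         WT  planarity  1.007101  0.028691  5
1       K95E  planarity  0.730916  0.028048  5
2       K67E  planarity  0.660232  0.018777  5
3       E60K  planarity  0.739437  0.034982  5
4       E87K  planarity  0.938439  0.016338  5
5  E60K/E87K  planarity  0.572989  0.021595  5
K95E 0.0 0.0079 ##
K67E 0.0 0.0079 ##
E60K 0.0 0.0079 ##
E87K 4.0 0.0952 ns
E60K/E87K 0.0 0.0079 ##
```

The planarity ratio (methine 1586 over ν₄ 1368 height, reduced state) drops
for every substitution near the heme — most strongly for the E60K/E87K
double mutant — while E87K, whose substitution lies far from the heme, stays
statistically indistinguishable from the wild type (exact Mann–Whitney,
n = 5 vs 5; `##` means p < 0.01, the smallest attainable two-sided p being
2/252 ≈ 0.0079 at complete separation).

## Analysis scripts

`analysis/01…05` run the whole study workflow on simulated cohorts and write
tables under `results/`: simulate (01), baseline-correct and quantify bands
(02), compute ratio indices with mean ± SEM summaries (03), run all group
comparisons (04), and validate parameter recovery, effect-direction
reproduction and the exact test's type-I error by Monte Carlo (05).

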