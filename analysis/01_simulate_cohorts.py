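#!/usr/bin/env python
"""Simulate replicate Raman/SERS cohorts for every study condition.

Generates n = 5 replicate spectra per variant with the `paper_like` preset —
neuroglobin (WT + 5 mutants) and cytochrome c (WT + 3 mutants), each oxidized
(SERS) and reduced (RRS) — and writes them as two-column CSV files with JSON
metadata sidecars plus a ground-truth file of the latent conformational
states, under results/simulated/.
"""

import json
from dataclasses import asdict
from pathlib import Path

from hemeraman import ConformationState, Protein, Redox, generate_cohort, paper_like_deltas, write_spectrum

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 42
N_REPLICATES = 5

conditions = [(p, r) for p in (Protein.NGB, Protein.CYTC) for r in (Redox.OXIDIZED, Redox.REDUCED)]

OUT.mkdir(parents=True, exist_ok=True)
truth = {}
n_files = 0
for i, (protein, redox) in enumerate(conditions):
    deltas = paper_like_deltas(protein)
    wt = ConformationState(protein, redox)
    spectra = generate_cohort(wt, deltas, n_replicates=N_REPLICATES, seed=SEED + i)
    for sp in spectra:
        safe_variant = sp.meta.variant.replace("/", "-")
        name = f"{protein.value}_{redox.value}_{safe_variant}_r{sp.meta.replicate}.csv"
        write_spectrum(sp, OUT / name, dialect="csv_with_header")
        n_files += 1
    truth[f"{protein.value}_{redox.value}"] = {
        v: asdict(ConformationState(protein, redox, **d)) for v, d in deltas.items()
    }

(OUT / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
print(f"wrote {n_files} simulated spectra (+ sidecars) and truth.json to {OUT}")
print(f"conditions: {[f'{p.value}/{r.value}' for p, r in conditions]}, n = {N_REPLICATES} per variant")
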