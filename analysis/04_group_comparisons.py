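#!/usr/bin/env python
"""Mutant-vs-WT and mutant-vs-mutant comparisons of every ratio index.

Applies the exact Mann–Whitney test (n = 5 per group) within each
(protein, redox) condition and writes results/comparisons.csv with the
figure-annotation markers: #/## for mutant vs wild type (p < 0.05 / 0.01),
*/** for mutant pairs.  Prints the significant wild-type contrasts.
"""

from pathlib import Path

import pandas as pd

from hemeraman import compare_all
from hemeraman.stats import comparisons_to_frame

RESULTS = Path(__file__).resolve().parent.parent / "results"

tab = pd.read_csv(RESULTS / "metrics.csv")
frames = []
for (protein, redox), sub in tab.groupby(["protein", "redox"]):
    res = comparisons_to_frame(compare_all(sub, reference="WT"))
    res.insert(0, "protein", protein)
    res.insert(1, "redox", redox)
    frames.append(res)
comparisons = pd.concat(frames, ignore_index=True)
comparisons.to_csv(RESULTS / "comparisons.csv", index=False)

sig = comparisons[(comparisons.vs_reference) & (comparisons.marker != "ns")]
print(f"{len(comparisons)} comparisons written → comparisons.csv")
print(f"\nsignificant wild-type contrasts ({len(sig)}):")
for _, r in sig.sort_values(["protein", "redox", "metric"]).iterrows():
    print(
        f"  {r.protein:4s} {r.redox:8s} {r.metric:16s} {r.group_a:10s} vs WT  "
        f"U={r.u_statistic:4.1f}  p={r.p_value:.4f}  {r.marker}"
    )
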