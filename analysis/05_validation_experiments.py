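#!/usr/bin/env python
"""Monte-Carlo validation of the whole pipeline against generator truth.

Three experiments: (1) parameter recovery — the computed planarity ratio must
track the latent planarity multiplier; (2) direction-of-effect reproduction —
how often the configured mutant effects are flagged at p < 0.05 over repeated
cohorts, including the no-effect K72E control; (3) type-I error of the exact
Mann–Whitney test under the null.  Writes results/validation.csv.
"""

from pathlib import Path

import pandas as pd

from hemeraman.validation import direction_of_effect_rates, null_type1_error, planarity_recovery_curve

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7

rows = []

curve = planarity_recovery_curve(multipliers=(0.5, 0.75, 1.0), n_seeds=20, seed=SEED)
print("parameter recovery (mean planarity ratio per latent multiplier):")
for mult, mean in curve.items():
    print(f"  multiplier {mult:4.2f} → computed ratio {mean:.3f}")
    rows.append({"experiment": "planarity_recovery", "case": mult, "value": mean})
assert curve[0.5] < curve[0.75] < curve[1.0], "recovery curve must be monotone"

rates = direction_of_effect_rates(n_cohorts=200, seed=SEED)
print("\ndirection-of-effect flag rates over 200 cohorts (p < 0.05 vs WT):")
for variant, rate in rates.items():
    print(f"  {variant:10s} {100 * rate:5.1f}%")
    rows.append({"experiment": "direction_of_effect", "case": variant, "value": rate})

t1 = null_type1_error(n_simulations=2000, seed=SEED)
print(f"\nempirical type-I error of the exact test (n = 5 vs 5, α = 0.05): {t1:.4f}")
rows.append({"experiment": "null_type1_error", "case": "n5_alpha05", "value": t1})

pd.DataFrame(rows).to_csv(RESULTS / "validation.csv", index=False)
print("\nwrote validation.csv")
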