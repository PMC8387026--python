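"""Hatching-assay statistics: dose-response and stage sensitivity score.

Builds a synthetic dose-response table (binomial counts over increasing LED
intensities) and the synthetic stage-shift example table, then prints the
per-intensity viability summary and the per-stage sensitivity score
(weighted mean of dark-relative viabilities, 0 = most sensitive stage).
"""

import pandas as pd

from lexykit import dose_response, example_hatch_table, sensitivity_score, synth_hatch_table

dose = synth_hatch_table(
    {"0": 0.90, "20": 0.75, "40": 0.55, "60": 0.35, "80": 0.15, "100": 0.05},
    n_embryos=50, n_replicates=3, genotype="iLEXYs", seed=1)
summary = dose_response(dose)
print("viability vs LED intensity (mean +- SD over replicates):")
print(summary.round(3).to_string(index=False))
print(f"\nmonotonicity diagnostic: Spearman rho = "
      f"{summary['spearman_rho'].iloc[0]:.2f} (negative = light kills)")

table = example_hatch_table(seed=7)
rates = table.assign(rate=lambda d: d["hatched"] / (d["hatched"] + d["unhatched"]))
v = rates.pivot_table(index="stage", columns="condition", values="rate")
weights = table.groupby("condition")[["hatched", "unhatched"]].sum().sum(axis=1)
scores = sensitivity_score(v, weights)
print("\nstage sensitivity scores (0 = most sensitive to nuclear depletion):")
print(scores.round(3).to_string())
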