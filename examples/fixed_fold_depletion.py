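"""Fixed-mode fold depletion: dark vs blue-light z-stacks.

Renders 30 dark and 30 lit cells at the slow-variant steady-state N/C
ratio pair, quantifies each cell over three consecutive z-planes with
background subtraction, and reports the fold reduction in mean N/C ratio
with a seeded bootstrap confidence interval.  The slow-cycling variant is
the most efficient depleter (~31-fold); the original construct reaches
~13-fold.
"""

from lexykit import run_fixed_experiment

for preset in ("fixed-iLEXYs", "fixed-LEXY"):
    res = run_fixed_experiment(preset, n_cells=30, seed=1)
    fc = res.fold
    print(f"{preset}: mean dark N/C = {res.dark_ratios.mean():.3f} "
          f"(n={fc.n_dark}), mean lit N/C = {res.lit_ratios.mean():.3f} "
          f"(n={fc.n_lit})")
    print(f"  fold reduction = {fc.fold:.1f}  "
          f"[95% bootstrap CI {fc.ci_low:.1f} - {fc.ci_high:.1f}]")
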