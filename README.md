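# lexykit

Simulation and quantification toolkit for **LEXY-type optogenetic
nuclear-export experiments** — for researchers who deplete nuclear proteins
with blue light and need to quantify how fast, how deep, and with what
phenotypic consequences.

A LEXY construct embeds a nuclear export sequence (NES) in the Jα helix of
the blue-light-sensitive *As*LOV2 domain. Blue light unwinds the helix,
exposes the NES, and CRM1 exports the fused protein from the nucleus; in the
dark the helix refolds and import restores the nuclear pool. Slow-cycling
LOV2 point mutants (the *iLEXY* variants) lengthen the dark reversion and
thereby both the recovery time and the depletion efficiency. The
experimental observable is the **nuclear/cytoplasmic (N/C) ratio** of
background-subtracted mean fluorescence density.

## The model and the quantification

The photocycle + transport model tracks the lit-state fraction *u* and the
nuclear/cytoplasmic amounts *N*, *C* (total conserved):

```
du/dt = (k_act·I_eff(t) + k_unf)(1 − u) − k_rec·u
dN/dt = k_imp·C − (k_exp0 + k_exp_lit·u)·N,      dC/dt = −dN/dt
```

with `I_eff` the duty-cycle-averaged blue-light intensity. Image stacks are
quantified per cell with whole-field bleaching normalization and background
subtraction:

```
Bleaching factor(tx) = [(RawIntDen/Area)_AllCells − (RawIntDen/Area)_BG]_tx
                     / [(RawIntDen/Area)_AllCells − (RawIntDen/Area)_BG]_t0
Fluorescence(tx)     = [(mean RawIntDen/Area)_compartment − (RawIntDen/Area)_BG]_tx
                        combined with the bleaching factor
Relative fluorescence(tx) = Fluorescence(tx) / Fluorescence_nucleus(t0)
```

Each phase of the N/C-ratio trace is summarized by a single-exponential fit
`y(t) = y_inf + (y0 − y_inf)·e^(−kt)` with half-time `t_1/2 = ln2/k`, and
dark/lit conditions by the fold reduction in mean N/C ratio with a bootstrap
CI. Hatching assays are summarized as dark-relative viability and a
stage-wise sensitivity score (weighted mean on [0, 1], 0 = most sensitive).

No external data are required: the `scene` module renders two-channel
synthetic microscopy (reporter + nuclear marker; Poisson + Gaussian noise,
per-frame bleaching, optional mitotic cells) with machine-readable ground
truth, and ROI tables exported from any image tool can be imported through
the documented CSV schema.

## Worked example

```sh
python examples/live_pipeline.py
```

```
cells quantified: 10, fits accepted: 10
median depletion half-time: 27.1 s (time for the relative N/C ratio to fall halfway to its plateau)

per-cell fits:
 cell_id    y0  y_inf   rms  t_half_s
       1 0.994  0.317 0.007    27.874
       2 0.995  0.316 0.006    27.311
       ...
```

This renders a 10-cell induction time-lapse (frames every 30 s, 10 min of
continuous blue light) with the slow-cycling `live-iLEXYs` preset —
calibrated so the noise-free N/C ratio halves its excursion in 25 s — then
segments nuclei from the marker channel, quantifies the bleach-corrected
relative N/C ratio per cell, and fits each cell's depletion. The median
fitted half-time (here 27.1 s) recovers the generating kinetics through the
full noisy pipeline and sits below the 30-s benchmark for these constructs.
`y0 ≈ 1` and `y_inf ≈ 0.32` say the ratio falls to about a third of its
dark value in live imaging; fixed-mode quantification
(`examples/fixed_fold_depletion.py`) resolves much deeper depletion
(13–31-fold depending on the variant).

Other examples: `photocycle_simulation.py` (model + LED protocols),
`viability_scores.py` (dose–response and stage sensitivity). A thin CLI
wraps the file-based pipeline:

```sh
lexykit run-all --preset live-iLEXYs --mode live --seed 1 \
    --n-cells 10 --frame-interval 30s --duration 10 --outdir run1
```

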