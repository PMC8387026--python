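# Methods

## Photocycle and transport model

The reporter is a nuclear protein fused to a LOV2 domain whose Jα helix
hides a nuclear export sequence. The model reduces the photophysics to a
two-state switch: a population fraction *u(t)* has the helix unfolded (NES
exposed, "lit state"), the rest is folded. Blue light drives unfolding at
`k_act·I_eff`, thermal fluctuation at `k_unf` (the origin of dark-state
activity), and the helix refolds at `k_rec` — the rate that distinguishes
the variants (slow-cycling point mutants have small `k_rec`). Transport of
the cargo between nucleus (*N*) and cytoplasm (*C*) is first order: import
`k_imp·C` and export `(k_exp0 + k_exp_lit·u)·N`. All rates are per minute.

Assumptions, in rough order of importance:

* **No synthesis or degradation** — the experiments quantify
  *redistribution* over minutes-to-hours, so the total `N + C` is conserved.
  The integrator enforces this structurally: only `(u, N)` are integrated
  and `C = total − N`, so conservation holds to machine precision and the
  Euler-oracle cross-check in the test suite verifies the dynamics
  independently.
* **Well-mixed compartments** — no spatial diffusion, no tissue-depth light
  attenuation.
* **Duty-cycle averaging** — pulsed illumination (e.g. 2 s on / 1 s off at
  70%) is averaged to `I_eff = I × duty` because pulse periods of a few
  seconds are far below photocycle timescales; `resolve_pulses=True`
  integrates the pulses exactly and the test suite confirms both agree.
* **Red-channel imaging does not activate the switch** — acquisition events
  affect the model only through bleaching.

`steady_state` gives the closed forms
`u* = (k_act·I + k_unf)/(k_act·I + k_unf + k_rec)` and
`ratio* = k_imp/(k_exp0 + k_exp_lit·u*)`.

## Rate calibration and the named presets

Experiments report *observable half-times* — the time for the noise-free
N/C-ratio trace to cross the midpoint between its initial value and its
asymptote under a step protocol — not rate constants. `calibrate_rate`
inverts the model by bracketing plus Brent root finding on a chosen free
rate (the half-time is monotone in each calibrated rate over the bracket),
to better than 0.1% relative.

The live presets share a backbone chosen to be realistic for an embryonic
nucleus: `k_imp = 0.5/min` (import timescale of a couple of minutes),
`k_unf = 0.001/min` (small but nonzero dark-state activity),
`k_act = 30/min` (activation essentially instantaneous at full intensity),
and a dark N/C ratio pinned at 3.0 via `k_exp0`. Per variant, `k_exp_lit`
is calibrated to a 25-s induction ratio half-time and `k_rec` to the
variant's recovery ratio half-time — 1.5 min (`live-LEXY`), 5 min
(`live-iLEXYi`), 50 min (`live-iLEXYs`) — by fixed-point iteration over
the three coupled constraints.

**A genuine limitation surfaced here:** for the fast-cycling original
construct the pair (25 s induction, 1.5 min recovery) has *no joint
solution* on this backbone. Dark-state transport relaxes at
`k_imp + k_exp0 ≈ 0.67/min`, which floors the ratio-recovery half-time near
2 min whenever the lit-state depletion is appreciable; the joint iteration
signals this by driving `k_rec → ∞`. Since the recovery half-time is the
variant's defining observable, `live-LEXY` is calibrated with recovery
exact and its induction half-time floats to the nearest attainable value
(~34 s). The slow-cycling variants calibrate jointly without tension.

A related modelling caveat: in this reduction, slower reversion (small
`k_rec`) *raises* the dark lit-state occupancy `k_unf/(k_unf + k_rec)`, so
the slow variant has the largest modelled dark-state export — the opposite
ordering to what is seen experimentally, where the slow variant has the
least dark activity. `k_rec` alone does not determine dark-state activity
mechanistically; per-variant `k_unf`/`k_exp0` remain configurable for users
who need that ordering. With the dark ratio pinned at 3.0 the choice does
not affect any quantity the pipeline reports.

The fixed-mode presets are dark/lit steady-state ratio pairs —
(2.6, 0.2), (3.2, 0.2), (3.1, 0.1) for the original, intermediate and slow
variants — whose quotients are the characteristic fold depletions 13, 16
and 31. The dark values are round choices; only the fold is meaningful.
Live and fixed presets are deliberately calibrated independently: live
imaging of these constructs systematically under-resolves the depletion
depth (weak signal, rapid bleaching, z-drift), so no cross-mode consistency
is asserted.

## Synthetic scenes

Cells are nucleus disks (radius 7 px) inside cytoplasmic annuli (outer
radius 13 px) on a jittered grid, non-overlapping by construction; 0.5 µm
pixels on a 256² field (384² when 30 cells are requested). Compartment
amounts map to mean pixel intensity with **equal volume proxies** (nuclear
mean ∝ N, cytoplasmic mean ∝ C), so the rendered intensity-density ratio
equals the model's amount ratio and ground truth is exact by construction.

Photometry defaults emulate a dim in-vivo reporter on a 16-bit detector:
background 100 counts, reporter scale 800 (dark-state nuclear mean ≈ 600
over background), marker 400. Noise is Poisson shot noise (gain 1) plus
Gaussian read noise (SD 3), then quantization to uint16. Bleaching is per
acquisition event — survival factor per frame (default 0.985 for the
reporter, matching the per-timepoint bleaching-factor correction downstream)
— not continuous in time. Mitotic cells are rendered condensed (half area)
and twice as bright in the marker channel so the exclusion heuristic has a
detectable signature. Everything is deterministic under the scene seed.

What the generator does **not** emulate: PSF blur and optical sectioning,
cell movement and z-drift, irregular cell shapes, intensity gradients across
the field, or expression variability between cells. Passing tests therefore
demonstrate that the quantification chain is correct and unbiased under the
stated noise model — not that segmentation or tracking would survive the
hardest real embryo data.

## Segmentation and ROIs

Marker frames are segmented by Gaussian smoothing (σ = 2 px) → Otsu
threshold → hole filling → distance-transform watershed → area filter.
Nuclear ROI = label eroded by 1 px; cytoplasmic ROI = annulus between
dilations by 2 and 5 px, minus all nuclei and a 2-px border margin;
background = pixels farther than 15 px from every nucleus; AllCells = union
of all per-cell ROIs. Whole-compartment masks replace manually drawn
sub-ROIs because they are deterministic and lower variance; an emulation
mode (`n_sub_rois`) samples seeded random disk sub-ROIs per compartment and
averages their densities. Tracking is greedy nearest-centroid matching to
frame 0 (cells are near-stationary at this timescale). Mitotic flagging
uses condensed-core features (pixels above half-max within each label —
whole-mask features are diluted by the smoothing halo): flag when core area
< 0.7× the median *and* core intensity > 1.5× the median; a cell flagged in
any frame is excluded throughout.

## Quantification

Implemented exactly as in the package docstrings: per-frame whole-field
bleaching factor, per-compartment mean of per-ROI densities, background
subtraction, normalization by nuclear fluorescence at t0. Two bleaching
modes exist because the multiplicative form of the fluorescence equation
circulates in protocol write-ups even though a survival factor < 1 then
*aggravates* the decay; the default divides ("corrected"). The N/C ratio —
the headline observable — is provably identical between modes (the factor
cancels), and the suite asserts this to 1e-9. Density averaging is mean of
`RawIntDen_i/Area_i` (robust to unequal ROI sizes). Invalid time points
(background-subtracted density ≤ 0) are dropped, never interpolated.
Fixed-mode ratios average densities over three consecutive z-planes before
background subtraction; the background region is distance-based (a
user-supplied BG mask can be passed through the measurement table instead).

## Kinetics estimation

Single exponential with plateau per phase, nonlinear least squares with
endpoint + log-linearized initial guesses; fits with fewer than 5 points,
no convergence, or a rate pinned at the search bounds are rejected.
Half-times are reported as the per-cell median (robust to dropout); the
mean-trace fit is also available.

**Estimator limitation, quantified:** the model's ratio recovery is not
single-exponential — in the reversion-limited regime it has the shape
`1/(a + b·e^(−kt))` with a transport lag — so the fitted `ln2/k` and the
midpoint-crossing half-time disagree at the 5–20% level, with sign and
size depending on the observation window (measured noise-free: +15% for
the slow variant observed for 3 recovery half-times, −11% for the
intermediate variant over 4). This is inherent to summarizing a
two-timescale process with one rate, matches how such half-times are
conventionally reported, and is why the recovery parameter-recovery tests
assert agreement at 20%, while induction (effectively single-stage once the
fast photoswitch equilibrates) is asserted at 10%.

Fold changes are quotients of condition means with a seeded nonparametric
bootstrap CI (2000 resamples); recovery endpoints use the closed form
`−ln(1 − f)/k`, with the "full recovery" threshold configurable (default
0.9) rather than asserted at any particular value.

## Viability statistics

Viability = hatched/(hatched + unhatched), unfertilized excluded. Relative
viability is the quotient of mean rates with first-order error propagation.
The sensitivity score's weights are not prescribed by the assay description;
the default weights each exposure condition by its total embryo count (the
natural precision weight for binomial data, given typical replicate sizes
of 15–40 embryos), with equal weights as an alternative. "Scaled from 0 to
1" is read as clipping of the weighted mean (dark-relative viabilities are
naturally in [0, 1] up to noise); min–max rescaling across stages is
provided as a second mode. Both choices are interpretations, flagged as
such in the API docs.

## Numerical choices

* ODE integration: LSODA, rtol 1e-10 / atol 1e-12, piecewise over protocol
  segments; dense output + Brent for midpoint crossings.
* Calibration: bracketing by geometric expansion, Brent to rtol 1e-6 on the
  rate; preset fixed-point iteration converges to < 0.05%.
* Seeds: every stochastic component takes an explicit seed; composite runs
  derive child seeds via `numpy.random.SeedSequence` spawning (kept below
  2³¹). Identical config + seed ⇒ byte-identical outputs.
* Degenerate inputs: flat frames segment to zero labels; empty ROI masks,
  zero-signal scenes, all-zero weights, constant traces and sub-minimum
  point counts raise typed errors or mark the affected cell/time invalid
  with a warning, as documented per function.

## Problem sizes

Default study conditions: 10 cells per live run (256² field), 30 cells per
fixed condition (384²), frames every 30 s for induction (10 min continuous
light), recovery sampled at 15 s / 30 s / 2 min for the fast / intermediate
/ slow variant over 8 / 20 / 150 min, three z-planes in fixed mode, 2000
bootstrap resamples. These sizes resolve all reported quantities with
seed-to-seed variation well inside the stated tolerances.
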