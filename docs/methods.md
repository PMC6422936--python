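# Methods

This note documents the models behind `muc3`, the parameters that matter,
the numerical choices, and what the synthetic data can and cannot say about
real experiments.

## Device model

The chip is modelled as a set of axis-aligned regions in the plane, in
micrometres: a central loading channel (100 µm wide, origin at its centre),
ten 900-µm migration channels per side at 100-µm pitch (10 µm wide),
absorbing chemoattractant reservoirs beyond each channel end, and vertical
maze "ladder" rungs bridging adjacent channels at five axial stations
(150–750 µm from the mouth). Boundary points resolve toward the more distal
region: a channel mouth belongs to the channel, a reservoir mouth to the
reservoir. The rung count, pitch and stations are not dimensioned in the
source figures; the values above were chosen to preserve the features that
matter for the read-outs (ten channels per side, 900 µm × 10 × 10 µm
channels, rungs attached only to migration channels) and are configurable.

## Gradient physics

Transport along a channel is 1-D diffusion with the reservoir end clamped
at the loading concentration (fMLP 10 nM, LTB₄ 100 nM). The loading end is
a perfect sink by default: the loading channel communicates with a media
bath orders of magnitude larger than the 10-µL reservoirs, so escaped
attractant is diluted away. This reproduces the observed linear steady
profile; a `finite_bath` option couples the end to a well-mixed volume
instead (400× the channel volume by default) for sensitivity checks.

Diffusion coefficients are estimated by Stokes–Einstein,
D = kT/(6πηr), at T = 310 K and η = 6.91 × 10⁻⁴ Pa·s (water at 37 °C),
with the empirical small-molecule radius law r = 0.059 nm · MW^⅓. This
gives D ≈ 733 µm²/s for fMLP (438 Da) and ≈ 800 µm²/s for LTB₄ (336 Da),
in the range typical for sub-kDa solutes; the radius coefficient is
exposed because it is the least certain constant in the chain.

The solver is Crank–Nicolson on a uniform grid (dx = 10 µm, dt = 1 s,
stored at 1-min resolution). The scheme is unconditionally stable, so step
sizes are set by accuracy: against the Fourier-series solution of the
fixed-boundary problem the worst-case error is < 3 × 10⁻⁵ of the reservoir
concentration (tested at 1, 5, 15, 60 and 300 min). "Gradient formed" is
operationalised as a maximum deviation from steady state ≤ 5% of the
reservoir concentration; with the Stokes–Einstein D this gives a 5-min
formation time for fMLP, comfortably inside the assay's loading window,
and the profile stays at steady state through the full 5-h experiment.
The maze attenuation acts on gradient steepness (10-fold), not on absolute
concentration, matching the device description.

## Migration model

No cell-behaviour model accompanies the assay, so the generator is this
package's construction: the minimal biased persistent random walk able to
express all five phenotype read-outs. Per 2.5-min step (matching the
imaging interval):

* An idle motile cell commits to migration with probability
  1 − exp(−a·dt), where `activation_rate` a (1/min) controls accumulation
  kinetics. It picks a side with odds `bias_strength × g` (g = normalised
  gradient steepness at the mouth), walks to the nearest channel mouth,
  then advances along the channel.
* Per-step speed is |N(v_cell, σ_step)|, where v_cell ~ N(speed_mean,
  speed_sd · speed_cell_fraction) is fixed per cell and
  σ_step = speed_sd · √(1 − speed_cell_fraction²). The split matters:
  per-cell variance spreads arrival times (flattening accumulation
  curves), per-step variance does not, while both leave the population
  mean path velocity at speed_mean.
* Headings persist; with probability `reversal_probability` the cell
  reorients and faces the reservoir with probability ½(1 + tanh(bias·g)).
  Oscillatory migration (≥ 3 direction changes) therefore emerges from one
  parameter rather than an explicit behavioural state switch.
* Crossing a channel–rung junction diverts the cell into the maze with
  probability `maze_entry_weight/(1 + attenuation)` per junction; in a
  rung the same walk runs vertically with the attenuated gradient, and
  either end returns the cell to a channel.
* Reservoirs absorb. Arrived cells drift monotonically to a per-cell
  parking spot inside the reservoir — this spreads them spatially (so
  rendered spots do not pile up) without ever reversing direction, which
  would otherwise contaminate the oscillation counts.
* Without chemoattractant the same machinery runs with the
  `spontaneous_fraction` pool, unbiased side choice and g = 0.

Cells are seeded uniformly in the loading channel with an 8-µm contact
exclusion. All randomness flows from one PCG64 generator seeded per run;
identical (preset, seed) gives bit-identical tracks.

## Preset calibration

The three packaged presets are calibrated, not derived: a grid search
(`muc3.calibrate.calibrate_preset`, driven by
`scripts/calibrate_presets.py`) minimises squared relative error between
pipeline outputs and the published per-condition summary statistics.
Speed means/SDs are taken directly from the published per-side velocity
table; motile fractions, activation rates and bias strengths absorb the
endpoint percentages and accumulation rates; reversal and maze-entry
parameters reproduce the oscillatory/lost trends (super-low ≫ high ≥
unstimulated), which are treated as trend targets only because the source
reports raw counts from unknown denominators (and with internal
inconsistencies). `docs/calibration.md` holds the achieved-vs-target
table. Published SDs describe day-to-day biological replication; the
simulator's replicate scatter is sampling noise at n = 500, which for the
sharply-peaked accumulation-rate statistics is wider than the narrowest
printed SDs (e.g. ± 0.30 %/h) — those comparisons use a ± 1 %/h band.

## Imaging and tracking

`render_frames` emulates Hoechst/DAPI nuclear imaging: one Gaussian spot
per cell (σ = 1.5 px at 2 µm/px) on a constant background with Poisson
shot noise and Gaussian read noise. Detection is single-scale
Laplacian-of-Gaussian filtering with local-maximum extraction and
intensity-weighted sub-pixel centroids; linking is greedy
nearest-neighbour with a displacement gate and gap closing (≤ 2 frames),
with a Hungarian-assignment mode for cross-checks. The gate defaults to
60 µm/frame (24 µm/min): the observed velocity distributions reach
~20 µm/min, and a tighter gate fragments the fastest tracks. On rendered
fixtures at ~100 cells/field the tracker recovers ≥ 95% of tracks with
sub-pixel localisation, and phenotype metrics from tracked images agree
with ground truth within 5%.

## Metric conventions

* The percent-migrated denominator is the loading-channel count averaged
  over *all* frames, including cells that later emigrate (a literal
  reading of the definition); it is shared by the spontaneous-migration
  metric.
* Rate of accumulation scans every frame-aligned 60-min window and
  reports the maximum OLS slope, in %/h.
* Velocity defaults to the in-channel scope (channel + maze samples on
  one side; only segments with both endpoints in scope count), because
  the published velocities are "toward" an attractant; whole-track scope
  is available. Cells with < 2 in-scope samples are excluded.
* Direction changes use a 2-µm jitter floor per axis (below half a
  channel width) so centroid noise does not inflate counts; the
  oscillatory, non-directional (maze-entering) and directional labels are
  non-exclusive flags.
* Decision ratios are taken at the final frame (300 min). Division by an
  empty reservoir returns an infinity sentinel with a defined-ness flag.
* Group comparisons: unpaired equal-variance Student's t-test at
  α = 0.05, Welch optional, no multiple-testing correction by default
  (Holm available as a flag), n = 3 replicates by convention.

## Problem sizes

Desk-scale defaults stand in for the wet assay's ~500,000 loaded cells:
500 cells × 3 replicates per condition, 121 frames at 2.5 min. All
percentage metrics are denominator-normalised, so they are
scale-invariant up to sampling noise (tested by doubling n). The
acceptance script runs the identical configuration.

## What the synthetic data does not capture

Cell–cell interactions (crowding, LTB₄ relay signalling between
neighbours), receptor-level adaptation and desensitisation, heterogeneous
sub-populations beyond the motile/non-motile split, cell death or
division, photobleaching, and any mechanism linking LPS dose to the
preset parameters — presets are phenomenological summaries of each
conditioning state. Passing tests therefore show that the pipeline's
measurements faithfully recover the behaviour of *this* generative model
at the published summary-statistic level, not that the model mechanism is
the one operating in cells.
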