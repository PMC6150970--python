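# Methods

## Problem and pipeline

`travelmode` assigns one of five travel modes — walk, cycle, vehicle, train,
stationary — to every 10-second epoch of a combined hip-worn accelerometer +
GPS recording. The pipeline is: read raw streams → summarise accelerometry
per epoch → merge GPS by timestamp → add rail-distance and displacement
features → smooth with moving windows → classify with gradient-boosted trees
→ evaluate with per-mode confusion-matrix metrics. Classification is
per-epoch: no prior segmentation into journeys is attempted, so a
mis-detected mode shift costs a few epochs rather than a whole trip.

## Epoch features

Raw tri-axial samples (g units, declared rate, default 30 Hz) are floored to
a UTC-anchored 10-s grid. The grid anchor is a convention, not physics; it is
configurable in principle but fixed to UTC flooring here so that epochs from
different devices align. Epochs holding less than 50 % of the expected
samples are dropped.

Per axis and epoch:

* **MAD** — `median(|v − median(v)|)`, unscaled. No 1.4826 consistency
  factor is applied: the statistic is used as a raw dispersion feature, and
  trees are invariant to monotone rescaling anyway.
* **10th / 90th percentile** — linear-interpolation ("type 7") quantiles.
* **Skewness / kurtosis** — moment-based g1 = m₃/m₂^1.5 and excess
  g2 = m₄/m₂² − 3. A zero-variance epoch returns 0 for both by convention
  (the limit of a symmetric degenerate distribution); estimator choice only
  shifts feature scale, which the trees absorb.
* **FFT mean strength** — the mean one-sided FFT magnitude of the demeaned
  signal, excluding the DC bin, normalised by epoch length. Excluding DC
  stops the 1 g gravity offset from dominating the feature; no frequency
  band-limiting is applied.

The per-epoch statistics are computed in a vectorised pass over equal-length
epochs; a test asserts bit-level agreement with the scalar reference
functions.

GPS fixes attach to the epoch whose `[start, start + 10 s)` window contains
their timestamp; the first fix wins if several fall inside (devices here log
every 10 s, so collisions are rare). GPS-derived features are speed (the
device-reported value when present, otherwise great-circle distance to the
previous fix over elapsed time), sumSNR (sum of per-satellite
signal-to-noise ratios; an empty satellite list sums to 0), and the distance
to the nearest rail line. Epochs without a fix keep NaN in all GPS-derived
columns.

## Non-wear detection

A 60-minute window, slid in 15-minute steps from the first sample, is
non-wear when the per-axis sample SD is below 13 mg on at least two axes;
flagged intervals are the union of qualifying windows, and epochs wholly
inside them are excluded from training and evaluation. The 15-minute step is
a resolution/cost compromise used by standard raw-accelerometry toolchains;
a brute-force oracle test pins the exact step-quantised behaviour. Note the
rule's known edge effect: a window straddling a wear/non-wear boundary can
qualify when the adjacent wear signal is very quiet, flagging some true wear
time.

## Geometry

Rail distance is computed analytically rather than through a GIS stack: each
query point anchors a local equirectangular frame (x = RΔλ·cos φ₀, y = RΔφ,
R = 6 371 000 m), and the minimum point-to-segment distance over all network
polylines is taken in that frame. At the ≤ 10 km scale of urban travel the
projection error against the great-circle distance is below 0.5 % (asserted
in tests), negligible against GPS noise. The batch variant shares one frame
anchored at the point-cloud centroid, which is what the pipeline uses for a
participant-day. No spatial index is built; a day of epochs against a
city-scale network is a few million segment tests, well under a second in
vectorised form.

## Window features

Each of the 18 per-axis accelerometer features and the speed is smoothed
over a **centred** ±2-minute window (default 4 minutes total) with four
statistics: mean, population SD, 10th and 90th percentile; sumSNR and rail
distance get a window mean. Centring uses both past and future context,
consistent with the forward-looking "distance over the next minute" feature;
windows shrink at recording edges and never cross a gap in the 10-s epoch
grid, so smoothing cannot blur across device-off periods. The statistics are
computed over the *epoch-level derived features* (e.g. over the ~24 MAD
values in a window), not over raw samples. Displacement features sum
fix-to-fix great-circle distances over `[t − 60 s, t]` and `[t, t + 60 s]`;
fewer than two fixes in a span give 0.

The final matrix has 101 columns in a fixed, documented order (raw features,
window statistics, displacement). Non-wear rows are always excluded; rows
without GPS either carry NaN in GPS-derived cells (the default — XGBoost
routes missing values natively) or are dropped with `require_gps`.

## Classifier

XGBoost multiclass (`multi:softprob`) with learning rate 0.1, 200 rounds,
row subsample 0.2, max depth 10, minimum split loss γ = 10 — a deliberately
conservative setting (half-strength updates, aggressive subsampling) chosen
against over-fitting. Class imbalance is left unweighted; stationary
dominates real recordings and the evaluation reports this honestly rather
than reweighting it away. Prediction takes the argmax of the five class
probabilities, with exact ties broken by the canonical order (walk, cycle,
vehicle, train, stationary). Training is single-threaded by default: with a
fixed seed this makes runs reproducible at the label level (asserted in
tests); under row subsampling, sampling is index-based, so *permutation* of
training rows is only guaranteed invariant with subsample = 1.0 and the
exact tree method, which is how the invariance test is configured.

Cross-validation assigns *participants* to five folds (seeded shuffle,
round-robin; sizes differ by ≤ 1), so no person contributes to both sides of
a fold — epoch-level folds would leak within-person autocorrelation and
inflate accuracy. The pooled confusion matrix is the elementwise sum over
folds. The moving-window-size sweep retrains on candidate windows
(1–5 minutes) and selects by the mean of walk and cycle F1 on held-out
participants disjoint from the training set.

## Evaluation

Confusion matrices are 5×5 with predicted mode on rows, observed on columns.
PPV = 100·TP/row-sum, sensitivity = 100·TP/column-sum, F1 their harmonic
mean; overall accuracy = 100·trace/total; mean sensitivity is the unweighted
mean over the five modes and active-travel sensitivity the mean of walk and
cycle. A mode never predicted (empty row) or never observed (empty column)
yields a *missing* metric, never 0 — zero-filling would silently deflate or
inflate summary means — and any mean over a missing value is itself missing.
Percentages are held at full precision internally and rounded half-up to one
decimal only when reported. Time-in-mode tables convert epoch counts to mean
minutes per participant (count × 10/60, averaged over participants).

## Synthetic cohorts

The simulator exists so the full pipeline can be exercised and validated
without any study data. Each participant-day is a *recorded window* (default
120 min) structured like a commuting day — stationary blocks, walking links,
one rail leg, one cycle leg, one vehicle leg with stop-go episodes — rather
than 24 h of idle samples: labelled training examples in this setting are
commute segments, so this is the regime that matters, and it keeps 30 Hz
synthesis tractable. Default contrasts:

* speeds (km/h): stationary ≈ 0, walk 4–6, cycle 12–20, vehicle 20–60 with
  10–30 s stops every 40–120 s, train 30–80 moving along rail polylines;
* accelerometer: 1 g gravity on z with slow orientation drift; walking a
  strong ~2 Hz oscillation (~0.35 g), cycling moderate ~1.4 Hz (~0.12 g),
  vehicle and train an *identical* low-vibration texture — on a hip-worn
  device the two metal-box modes are not separable by texture, so their
  separation must come from rail distance, sumSNR and speed;
* stationary wear time carries ~30 mg of postural fidget (real wearers never
  sit at the 13 mg non-wear floor), while inserted non-wear blocks (device
  removed after the recorded window, probability 0.3/day, 90 min) are
  near-constant at ~0.5 mg with no GPS;
* GPS: walk/cycle track 8–11 satellites at SNR ≈ 42 dB-Hz, vehicles 6–9 at
  ≈ 30, trains 5–8 at ≈ 24 with 25 % fix dropout, stationary/indoor 4–7 at
  ≈ 20 with 30 % dropout, plus a 2 % mode-independent dropout.

Per-participant streams come from spawned child seeds of the cohort seed, so
runs are bit-reproducible and cohorts of different sizes share no randomness
across participants.

The `degrade_train_cues` switch is a negative control: train segments take
the vehicle speed and SNR regimes and ignore the rail network, leaving only
the (shared) accelerometer texture. Train sensitivity collapses by tens of
points, demonstrating that the rail-distance and sumSNR features — not an
accidental artefact — carry train/vehicle separation.

**What passing tests do and do not show.** The simulator reproduces the
*statistical contrasts* the classifier is built on, with clean labels and
stylised dynamics. Real data add label noise at mode shifts, behavioural
diversity (slow cyclists, running, trams on roads), urban-canyon GPS
multipath, and device idiosyncrasies; cross-validated accuracy on synthetic
cohorts (typically > 95 %) therefore validates the pipeline's correctness
and the features' sufficiency under the stated model, not field performance.

## Problem sizes and numerical choices

The bundled end-to-end analyses use 10 participants × 2 recorded days
(≈ 14 400 epochs, 101 features) for parameter recovery and the negative
control, and smaller cohorts for unit-level checks — sizes chosen to keep a
full from-scratch run in the minutes range on a single core while leaving
every mode with thousands of labelled epochs. Distances use a fixed Earth
radius of 6 371 km; window SDs use the population convention (a singleton
window has SD 0, matching the shrinking-window edge case); timestamps are
UTC throughout, with an optional fixed per-file offset for devices logging
local time (offsets are never mixed within a participant). Malformed input
rows are skipped and counted, not fatal — field data are messy — and the
counts surface in logs.

## Known limitations

* The file dialects are documented stand-ins for ActiLife/Qstarz-style
  exports; binary device formats and NMEA are out of scope.
* The equirectangular rail distance degrades beyond ~100 km from the anchor
  (a warning fires); datum transformations and geodesic precision are out of
  scope.
* No bus/vehicle sub-discrimination, no journey segmentation, no imputation
  of missing GPS, and no statistical inference (CIs) on metric differences.
* The non-wear rule's boundary effect (above) can clip quiet wear time
  adjacent to true non-wear.
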