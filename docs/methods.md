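# Methods

This note documents the models, conventions and design choices behind
`sstclassify`, in the spirit of a package methods appendix. Nothing here
states an empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## Signal model and preprocessing

Each cell-day is a raw ROI fluorescence trace `F_ROI` with a paired
neuropil trace, sampled at 5.11 Hz by default. Neuropil contamination is
removed linearly, `F_corrected = F_ROI − r·F_neuropil` with `r = 0.7`.

**Motion shifts.** A frame is "shifted" when its registration displacement
exceeds 20 px in |dx| or |dy| (strict inequality). Runs of one or two
shifted frames are replaced by the mean of the nearest unshifted neighbors
on both sides (one side at a trace boundary, logged); the same fill is
available for the shift records themselves. Runs of three or more frames
are never interpolated and invalidate any trial window they overlap. The
boundary case of exactly three consecutive frames is grouped with
rejection — the conservative reading of "interpolate 1–2, reject > 3".
Inside spontaneous blocks, frames under long runs are masked (NaN) and
excluded from feature computation, paralleling the trial rule.

**Two ΔF/F₀ conventions.**

* *Trial convention:* per trial, `F₀` is the mean of `F_corrected` over
  the 1 s preceding onset; `ΔF/F₀ = (F − F₀)/F₀` over −3…+5 s. Trials with
  `F₀ ≤ 0` (possible after neuropil subtraction) are invalidated rather
  than clipped — ΔF/F is undefined there and clipping would fabricate
  signal. Trials whose window clips the recording edge are likewise
  invalid.
* *Spontaneous convention:* a per-frame `F₀` from a sliding 1-min
  20th-percentile filter, applied to the whole session. The window is
  centered and truncated at the edges; a centered window avoids startup
  bias on the 100-s flanking blocks (whether the original filter was
  centered or trailing is not specified; this is a pinned choice).

**Session segmentation.** Trial windows span −3…+5 s around each onset.
Spontaneous blocks are the complement: the initial block is the ≤100-s
window before the first trial window, intertrial blocks fill the gaps
between consecutive trial windows (≈12 s at the 20-s trial spacing), and
the final block is the ≤100-s window after the last. Blocks with
non-positive span are dropped; a session without trials is one initial
block. Second-valued windows are converted to frames by flooring
`t × frame_rate`.

## Feature grid

σ₁ is the population SD (divide by n) of the concatenated 1-s pre-onset
baselines of all valid trials; σ₂ is the population SD of the whole
session's spontaneous-convention ΔF/F₀. The population-SD convention is
pinned for reproducibility; at these sample sizes the n vs n−1 difference
is negligible.

The instantiated grid holds 126 unique first-order specs (the original
inventory of 117 lives in supplementary tables that are not part of the
main text; the grid here is the full cartesian structure of the main-text
parameter lists, shipped as an editable JSON manifest):

| category | structure | count |
|---|---|---|
| response probability | {stimulus, blank, all} × k ∈ {1,2,3,5,10}·σ₁ | 15 |
| in-trial | {stimulus, blank, all} × {pretrial −2…0 s, response 0…2 s, posttrial 2…4 s, full −3…+5 s} × {peak, latency, center of mass, AUC} | 48 |
| spontaneous events | {initial, intertrial, final} × {event peak, event count} × k ∈ 1…10·σ₂ | 60 |
| spontaneous AUC | {initial, intertrial, final} | 3 |

Conventions: the evoked-response window is 0…+2 s post-onset (0.5-s
stimulus plus GCaMP6f decay; configurable — the window is not pinned by
the source description). "Peak" is the raw ΔF/F₀ maximum within the
period. Center of mass uses positive-rectified ΔF/F₀ weights (negative
weights make it ill-defined); an all-nonpositive segment substitutes the
period midpoint and is flagged. AUC is the trapezoidal integral in
ΔF/F₀·s. Spontaneous events are local maxima whose topographic prominence
strictly exceeds k·σ₂ (`scipy.signal` peak prominences); with no events,
the mean event amplitude for that day is reported as 0. Per-unit values
(per trial, block or event) are averaged within day, then across ACC4–6;
cells missing any source day are excluded.

Feature ranking uses unpaired two-sample t-tests (Student, equal-variance)
between the genetic classes, sorted by p ascending; globally constant
features are flagged degenerate and sort last. The top 30 enter
classification.

## Classification

The top-30 matrix is z-scored per column (population SD; zero-variance
columns dropped), embedded in 2-D with UMAP, and clustered with k-means,
spectral clustering and DBSCAN over a hyperparameter grid
(default: n_neighbors ∈ {5,10,15,30}, min_dist ∈ {0,0.1,0.25,0.5},
k ∈ 2…8, 10 log-spaced eps values; a `full_*_grid` switch reproduces a
~5000-combination search, and a `small_*_grid` runs in seconds for tests
and examples — the exact original ranges are not published, so the grids
are documented stand-ins). Solutions are scored by silhouette on the
embedding coordinates (Euclidean — clustering operates on embeddings);
degenerate solutions (a single cluster, or silhouette undefined) are
discarded. DBSCAN noise points are excluded from the silhouette and can
never be assigned putative-Calb2. Selection is purely by silhouette among
non-degenerate solutions, optionally restricted to a chosen cluster count;
the original selection also weighed "consistency with the transcriptomic
hypothesis", which is not formalized and therefore not implemented —
the ranked solution list is exposed instead.

The cluster→subtype step operationalizes what was originally a manual
assignment: the cluster whose members have the highest mean stimulus
response probability and mean evoked peak (rank sum over the two criteria,
computed from the raw feature matrix) is putative SST-Calb2; ties break to
the lower cluster id with a warning, and a manual override is available.

Evaluation computes TP/FP/TN/FN with SST-Calb2 as the positive class and
the closed forms precision = TP/(TP+FP), recall = TP/(TP+FN),
F1 = 2PR/(P+R), accuracy = (TP+TN)/N, plus the analogous negative-class
precision/recall.

## Plasticity and behavior

The per-cell, per-day response is the mean over all valid stimulus trials
of the response-window ΔF/F₀ peak — all trials, irrespective of amplitude.
The ACC4–6 mean is the pretraining baseline (the first three acclimation
days are more variable and are not used); training epochs SAT1/2, SAT5/6
and SAT9/10 are reported as fold changes against it. Cells with
non-positive baseline are excluded; an epoch missing a day uses the
available day (logged), accommodating late-training data loss. Group
statistics: paired t-tests of epoch mean peak vs baseline with Bonferroni
correction over the number of epochs (corrected p = min(1, p·m)), and a
one-way repeated-measures ANOVA across days with cells as subjects
(`statsmodels` AnovaRM). The grouping level (cells vs animals) varies
across the study's own summaries; callers choose by pooling beforehand.
PSE experiments reuse the identical code path with PSE day labels.

Behavior: anticipatory lick frequency is the lick count in the 300 ms
before water delivery divided by 0.3 s. On blank trials (no water) the
window is anchored at the scheduled delivery time — onset plus 1.5 s, the
midpoint of the 0.2–0.8-s random delay plus the 0.5-s stimulus and 0.5-s
post-stimulus delay (whether the original analysis used scheduled or
matched-delay timing is not stated). Trials are grouped in 4-hour bins;
bins with fewer than 10 trials are removed. Performance is
`f_stimulus − f_blank` per bin. The per-day learning test takes the bins
covering the last 20% of the day's trials and applies a Wilcoxon
signed-rank test to their paired (f_stimulus, f_blank) values; with no
qualifying bins the day is excluded.

## Synthetic sessions

The generator's defaults are the study conditions: 5.11-Hz sessions with a
100-s opening spontaneous block, 30 trials at 20-s spacing (stimulus/blank
at equal probability, randomly interleaved — about 15 stimulus trials per
day, matching the deliberately minimal daily stimulus count), and a 100-s
closing block. Two subtypes by default: 28 Calb2-like cells
(response probability 0.8, median evoked peak 0.8 ΔF/F₀) and 56 others
(0.35, 0.3), mirroring the labeled-dataset proportions and the elevated
pretraining responsiveness of the Calb2 class. Per-class lognormal
amplitude dispersion (σ = 0.8) composes with the between-class gap to an
approximately 100-fold amplitude range across the population. Evoked
responses are Bernoulli-per-trial impulses scaled by the cell amplitude,
the day's suppression factor and mean-one trial jitter (σ = 0.1),
convolved with a GCaMP6f-scale kernel (τ_rise 0.05 s, τ_decay 0.7 s —
standard indicator-scale values, a generator convention). Spontaneous
events are Poisson (0.01 Hz) with amplitudes at half the cell's evoked
scale; suppression applies to evoked responses only (a flag extends it to
spontaneous activity for sensitivity analyses).

The Calb2-like suppression schedule is 1.0 through ACC and linearly
interpolates the training-day anchors SAT1 = 0.62, SAT5 = 0.56,
SAT10 = 0.46. Each cell additionally draws a mean-one lognormal
plasticity modifier (σ = 0.3) applied to its training-day factors and held
constant across days — cells differ in how strongly they suppress, and do
so consistently across the training period, as longitudinal tracking of
real SST neurons shows. This correlated heterogeneity also makes the
2-SEM recovery check statistically well-posed: with purely independent
per-day noise, the three epoch deviations are ~N(0, SEM²) with pairwise
correlation fixed near 0.4 by the 2-day-epoch / 3-day-baseline structure,
capping joint 2-SEM coverage near 88% regardless of noise scale. Because
the per-seed generated group suppression is then the ledger's realized
mean factor rather than the nominal schedule value, recovery tests compare
pipeline estimates against the ledger.

Clean fluorescence is `F₀·(1 + ΔF/F)` with per-cell lognormal baselines
(median 100 a.u., σ = 0.3); a slowly oscillating neuropil trace is mixed
into the ROI channel scaled by r = 0.7, so the standard correction
recovers the clean trace in expectation; Gaussian noise (σ = 1 a.u.,
i.e. ~1% ΔF/F) is added. Shift artifacts are injected as Poisson-count
runs (lengths 1, 2 or 5) of ±30-px displacements with a concurrent
fluorescence drop; a config flag makes artifacts drive `F_corrected`
negative to exercise the F₀ ≤ 0 error paths. mCherry intensities are
lognormal per subtype (Calb2-like median 400 a.u., others 80 a.u.),
straddling the 200-a.u. labeling threshold. A single brightness-scale
parameter (the baseline median) stands in for the transgenic-vs-viral
gain difference, whose magnitude is not constrained by the source text.

**What the generator does not emulate:** slow drift and bleaching,
behavioral-state covariates, spike-train temporal structure beyond linear
kernel convolution, cross-cell correlations, or segmentation errors.
Passing tests therefore demonstrate correctness of the pipeline's
computations and its ability to recover planted structure under realistic
noise — not classifier performance on real recordings, where overlapping
subtype distributions yield substantially lower accuracy.

## Problem sizes and numerical choices

The test suite and acceptance script run desk-scale versions of each
analysis as the package's own defaults: 50 generator seeds × 28 cells ×
9 days for suppression recovery; 20 seeds × 30 cells × 3 days with the
scaled-down embedding/clustering grid for cluster-count selection (the
three-subtype fixture uses tight within-class dispersion so the planted
structure, not sampling noise, drives the outcome). Determinism: all
randomness flows from explicit integer seeds through `numpy` Generators,
UMAP `random_state` and sklearn `random_state`; fixed seeds and grids give
bit-identical classifications. Degenerate inputs (no valid trials, empty
blocks, constant features, single-cluster solutions, empty classes) are
flagged or excluded rather than silently coerced, as described above.

## Known limitations

* The grid-search space and the 117-feature inventory are reconstructed
  from the main-text parameter lists, not the original supplementary
  tables/code; counts and ranges are documented but not identical.
* The cluster→subtype heuristic replaces a manual judgement; on data
  where putative subtypes do not differ in stimulus responsiveness it
  will warn and tie-break arbitrarily.
* The pooling of multiple fields of view per animal before averaging is
  exposed as an analysis choice (group by cell vs pre-pooled by animal)
  rather than fixed, since the original grouping level varies by figure.
* Repeated-measures ANOVA requires complete day coverage per cell;
  incomplete cells are dropped from that test (not from fold changes).
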