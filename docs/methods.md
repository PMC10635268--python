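# Methods

## Analysis model

The pipeline treats each ROI, group and session separately. Subject
voxel series are cleaned by a single least-squares projection onto a
nuisance basis: an intercept, a linear trend, the discrete-cosine drift
functions with frequencies below 1/140 Hz (K = ⌊2·T·TR/140⌋ columns),
and the supplied confound columns (six motion parameters, their
squares, derivatives and squared derivatives, plus a CSF regressor,
when available). Projecting jointly rather than sequentially guarantees
the residual is exactly orthogonal to every nuisance column and that
confound regression cannot reintroduce drift. Residual rows are
z-scored with the population SD; rows whose residual is numerically
zero relative to the input (a voxel equal to a nuisance column) are
defined to be exactly zero rather than amplified round-off noise, and a
z-score of a constant series likewise returns zeros with a warning.

The global component is each subject's average over all retained
gray-matter voxels (analyzed ROIs plus any unassigned voxels), z-scored
and computed *after* cleaning; the choice of computing it after
confound regression is recorded in the run manifest. Selective
components are per-voxel residuals after regressing on the global
component, z-scored.

The k = 1 shared response model minimizes Σᵢ‖Xᵢ − wᵢ s‖² under
‖wᵢ‖ = 1 by alternating updates (wᵢ = Xᵢs/‖Xᵢs‖, s = N⁻¹Σᵢ wᵢᵀXᵢ),
which makes the objective non-increasing; convergence is declared at a
relative objective change below 1e-8 (at most 100 iterations).
Initialization is deterministic — the leading principal direction of
the subject-stacked data, found by power iteration started from the
mean voxel signal — so the fit needs no random seed. The sign of s is
fixed to correlate non-negatively with the across-subject mean voxel
signal. Downstream statistics use the per-subject projections wᵢᵀXᵢ
(z-scored) rather than s itself, because the bootstrap, the leave-one-
out ISC and the subject-level correlations all require per-subject
series. The SRM is fit per group *and* session, so alignment cannot
leak session information.

Synchronized-TR detection is one-sided (positive median deflections),
following the threshold definition "CI above the null percentile"; a
mirrored negative test exists behind `detect_negative` but is off by
default. The bootstrap CI is a simple percentile interval over 5000
subject resamples; the null is the distribution of the maximum over
TRs of the surrogate group median under independent phase
randomization of every subject (5000 draws). Phase randomization
preserves each amplitude spectrum exactly (DC and Nyquist bins stay
real), hence autocorrelation and mean. A TR enters T\* when the lower
CI bound strictly exceeds the 95th percentile of the null maxima; ties
break toward non-detection. Bootstrap and null draws come from
independent named substreams of the stage seed, so changing the
bootstrap depth does not perturb the null.

Reverse correlation maps a post-drop TR index t to movie time
m = t + 10 (restoring the dropped initial TRs) and collects the bins
[m − 10, m − 5), i.e. the 5-second clip 5–10 s before the response;
bins outside the movie are discarded and the union over T\* is taken.
Bias = labeled fraction of the covered unique bins; the denominator is
the surviving unique bins. The permutation null redistributes each T\*
uniformly without replacement over the analyzed TR range, preserving
its size but not its autocorrelation (the reference procedure's
"randomly distributing the same number of bins"); p-values are
two-sided with the +1 correction, so p ∈ (0, 1]. ROIs with any empty
T\* give an undefined statistic and are excluded from the BH-FDR family
rather than assigned p = 1. Permutation depth defaults to 5000 (one
description of the procedure says 10,000; the more specific one says
5000, and the count is configurable and recorded in the manifest).
Baseline and delta tests use independent permutation streams.

Leave-one-out ISC correlates each subject with the mean of the others;
per-ROI values are Fisher-z transformed, averaged over the configured
OFC ROI set, and inverse transformed. Craving correlations are Pearson
r at baseline and between session deltas (follow-up minus baseline for
both variables), BH-FDR over the measure × {baseline, delta} family.
The Wilcoxon signed-rank helper drops zero differences, uses mid-ranks,
and computes exact p by dynamic programming over doubled ranks (exact
even with ties) up to 25 nonzero differences, else a tie-corrected
normal approximation. The two-sample t from summary statistics is the
classic pooled form with df = n₁ + n₂ − 2.

## Synthetic data

The generator emulates the study design: two groups (default 30 and 25
subjects), two sessions, 1033 acquired TRs at 1 s (1023 analyzed after
the 10-TR drop, matching the 1023-second movie), and a binary drug
label track with exactly 464 of 1023 bins labeled (45.4%). Tracks are
alternating geometric blocks (mean labeled-block length 8 s) adjusted
at run boundaries to hit the target count exactly. Each contiguous
block carries a salience gain drawn uniformly from (0.3, 1.7), shared
by all subjects, groups and sessions — scenes differ in intensity, and
without this the two-level drive has almost no peaks for a
max-statistic detector to find.

Voxel series are
`coupling · loading · (HRF ⊗ drive) + 0.5 · global + confound leakage + N(0, 1)`
on the pre-drop grid. The HRF is the canonical double-gamma (gamma
shapes 6 and 16, undershoot weight 1/6, peak ≈ 5 s), normalized to
unit sum inside the generator so amplitudes read as plateau response
levels in noise-SD units. Voxel loadings are U(0.5, 1.5); per-subject
couplings are U(0.3, 1.7), fixed across sessions — the subject trait
that both synchronization and craving inherit. (Coupling spread is a
genuine trade-off: wider spreads give the ISC-craving link more
between-subject signal but widen the bootstrap CI of the group median
and so cost detection power; ±70% is the chosen balance.) The global arousal
component is smoothed white noise shared within a group-session;
confounds are standardized random walks (six motion-like plus one
CSF-like) that leak into every voxel with small random weights, so the
confound regression has real work to do. A pool of unassigned
gray-matter voxels (default 400) carries only global + leakage +
noise; it enters the per-subject global average, which keeps the
global estimate from being collinear with any single ROI's stimulus
drive — emulating a whole-brain average over ~10⁵ voxels, where no
single ROI's response dominates.

Three ROI classes differ only in their drive:

* **Drug-locked ROIs** (default 0–2) respond to the drug track with
  group × session drug amplitudes ((1.5, 0.5), (1.5, 1.5)) against a
  flat non-drug level of 0.95. Since analysis series are z-scored,
  only the drug/non-drug contrast matters: the clinical group flips
  from +0.55 (drug-locked peaks) to −0.45 (weaker, non-drug-locked
  peaks), the control group stays at +0.55. The near-balanced
  magnitudes keep all four group × session cells detectably
  synchronized — a cell with an empty T\* would make the delta test
  undefined — while the sign flip moves the drug bias from high to low
  in the clinical group only. The unassigned gray-matter pool must
  stay large relative to the ROI voxels: the per-subject global
  average otherwise acquires a coupling-scaled stimulus component,
  and regressing it out both strips the planted drive and leaves
  coupling-dependent arousal residue that corrupts the ISC gradient.
* **OFC-like ROIs** (default 3–8) carry the same group × session
  structure against a non-drug level of 0.85, all scaled by 0.35.
  The scaling places them in the steep, unsaturated part of the
  ISC-versus-coupling curve, where between-subject ISC variation is
  informative; in strongly driven ROIs every subject's ISC saturates
  near 1 and the between-session ISC change stops being monotone in
  coupling. This mirrors the real separation between the regions that
  carry the strongest group bias effects and the ROI set whose
  aggregated ISC is related to behavior.
* **Background ROIs** (the rest) respond, with group- and
  session-invariant amplitudes (1.5/0.85), to their own independent
  label tracks (fraction 1/2, same block statistics) — different
  regions track different content features. This both makes
  specificity a genuine test (they synchronize, but carry no group
  effect) and decorrelates the global average from the drug drive.

Craving: scene-induced craving is
`3 + 8 · κ + N(0, 0.38)` clipped to [0, 10], where κ = coupling ×
(session drive SD of the OFC-like ROIs). The link runs through the
*planted* coupling, not the realized ISC, so recovering the ISC-craving
correlation is a genuine inference. The truth record stores the
planted delta correlation analytically,
ρ = slope·sd(Δκ) / √(slope²·var(Δκ) + 2·noise²), from the realized
couplings. The craving scale is continuous on [0, 10] (the discrete
0–9 in-scanner scale is not reproduced; a discretized scale would
coarsen the planted correlation). Other behavior columns
(pre-movie craving, movie-induced craving, HCQ total) are generated
independently of coupling as control measures.

What the generator does *not* emulate: spatial structure and smoothing
(ROIs are voxel index sets, not volumes), head-motion artifacts in
image space, physiological noise spectra, non-binary or overlapping
content labels, session-specific movie edits, and subject dropout.
Passing tests therefore demonstrate the statistical machinery under
the stated generative model, not robustness to those realities.

## Validation experiments and problem sizes

`cuesync.experiments` holds the standing validation studies; the test
suite and `scripts/acceptance.py` run them at sizes chosen to finish
comfortably on one CPU:

* **FWER calibration**: 200 replicates (100 in the script) of a
  15-subject group, 300 analyzed TRs, 20 ROIs of 4 voxels, all
  stimulus amplitudes zero; 1000 phase randomizations and 300
  bootstrap resamples per ROI. The fraction of ROI analyses with any
  detection must stay within two binomial SEs of 5%. The detector is
  in fact conservative (requiring the CI bound, not the median, to
  clear the max-null), so rates well below 5% are expected.
* **Permutation oracle**: 6 valid TRs, |T\*| = 2 per group, a fixed
  16-bin track; the 225 equally likely placements are enumerated with
  plain set arithmetic and compared with the 5000-draw Monte-Carlo
  p-value within three Monte-Carlo SEs.
* **Delta recovery**: 50 replicates (30 in the script) at 15 subjects
  per group, 600 analyzed TRs, 11 ROIs (3 drug-locked, 6 OFC-like, 2
  background) of 60 voxels, with a 1200-voxel unassigned pool (scaled
  with the ROI voxels to keep the global average arousal-dominated)
  and the OFC amplitude scale adjusted to 0.286 so that set sits in
  the same ISC regime as at the 40-voxel default; detection at 500
  bootstrap / 500 phase draws, tests at 2000 permutations, FDR
  q = 0.05. Sensitivity counts flagged drug-locked ROIs, specificity
  counts unflagged background ROIs (OFC-like ROIs carry a real scaled
  effect and belong to neither count). The same replicates estimate
  the group-A correlation between the OFC ISC delta and the
  scene-craving delta and check 95% Fisher CI coverage of the planted
  value.

Resampling depths below the 5000-draw analysis defaults are used only
in these replicated validation studies, where Monte-Carlo error of the
*procedure under test* (not of the validation verdict) is the relevant
scale; single-analysis runs default to 5000 everywhere.

## Numerical choices and edge cases

* Population-SD z-scoring throughout; constant series map to zeros.
* Bootstrap medians and surrogate maxima are computed in float32 (the
  resampling noise dwarfs the rounding); `phase_randomize` itself is
  float64 and spectrum-exact to 1e-10.
* The bootstrap/null inner loops use numba kernels when importable
  (weighted-median walks over pre-sorted columns; a screen-then-median
  max reduction); numpy fallbacks give the same results.
* Fisher aggregation rejects |r| = 1; callers clip leave-one-out ISC
  at 1 − 1e-6 before aggregating.
* Permutation p-values use the +1 correction and a 1e-12 tie tolerance
  when comparing |null| ≥ |observed|.
* Empty T\* propagates as NaN statistics, excluded from FDR.
* The pipeline's config rejects unknown keys anywhere, since a typo in
  a resampling count is the main silent reproducibility hazard.

## Known limitations

* One shared component per ROI: genuinely multi-dimensional shared
  responses are collapsed.
* The uniform-placement permutation null ignores T\* autocorrelation; a
  block-preserving variant is not implemented.
* The detector's FWER control is conservative; its power against weak,
  sustained (plateau-like) synchronization is limited by design of the
  max-statistic null — transient, scene-locked responses are what it
  detects well.
* Sample-description utilities cover the pooled t and the signed-rank
  test only; they are not a general statistics layer.
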