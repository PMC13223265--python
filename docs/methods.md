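# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what the synthetic-data tests do and do not establish about
real data.

## Behavioral model

Ratings are continuous visual-analog responses in [0, 100] sampled while a
narrative unfolds. The preprocessing chain assumes: (1) samples before a
rater's first mouse move carry no signal and are set missing; (2) linear
interpolation onto a uniform grid (default 230 ms, half the scanner TR) is
adequate because rating dynamics are slow relative to the grid;
(3) the group median is the summary of interest, with a raw MAD band
(median ± 1.96·MAD/√n, no 1.4826 normal-consistency factor) and the median
of an even count taken as the mean of the two central values. A timepoint
is invalid when fewer than 50% of retained raters have a value; a rater is
dropped from a trial below 40% coverage.

Exclusion rules, in order: more than 2 of 4 failed attention checks; a
constant response across all non-missing samples; correlation with the
leave-one-out median below threshold (defaults 0.3 for the social
question, 0.2 for ToM engagement). The leave-one-out form follows from
comparing each rater against *all other* raters, not the full-cohort
median. Exclusion is one pass, not iterated.

Reliability is the Spearman–Brown corrected split-half correlation of
half-cohort means (2r/(1+r)), over 2000 unstratified random equal splits
(odd cohorts drop one rater per split); timepoints with any missing value
are removed listwise before all correlations. Pairwise inter-rater
correlations (median, MAD) are reported as the more conservative
similarity measure.

The phase-randomization surrogate test randomizes the Fourier phases of
the second (annotation-derived) series with conjugate symmetry, leaving DC
and Nyquist untouched, so mean and amplitude spectrum are preserved
exactly. The two-sided p is the fraction of surrogates with |r| at or
above the observed |r|, floored at 1/n_surrogates (default 10,000).

## Design and first level

The canonical HRF is the double-gamma difference Γ(6,1) − (1/6)·Γ(16,1),
32 s long, peak-normalized; its mode falls at ~5 s. Convolution runs at
the behavioral grid resolution and is decimated to volume onsets (TR must
be an integer multiple of the grid step; alignment is onset-based and the
convolved regressor is left uncentered — both exposed in config). Plain
discrete convolution is used; its amplitude scale cancels in every t-based
statistic downstream.

Nuisance structure: K = ⌊2·n·TR·cutoff⌋ discrete-cosine columns per run
(cutoff 1/128 Hz); 24 motion regressors (6 parameters, backward-difference
derivatives with leading zero, squares of both); a CSF mean-signal column;
one unit-indicator column per outlier volume, flagged where the run-wise
|z| of global signal or framewise displacement exceeds 3 (single-pass
mean/SD, strict inequality); one unit-indicator per volume lacking a valid
group rating. The first 6 volumes of every run are discarded from data and
all regressors after convolution, so HRF tails crossing the cut are
truncated consistently; indicator columns that land in the discarded head
are dropped. Runs are grand-mean scaled to 100 and concatenated; interest,
rating-period, and demand-pair columns are global (one beta each), all
other columns per run. Collinearity is auditable via VIF_j = 1/(1−R²_j)
on any column subset; rank deficiencies raise with the offending columns
named rather than returning infinities.

## Second level, conjunction, and Bayes factors

Group inference is a one-sample t-test per voxel over participant betas
(sample SD, n−1, everywhere — also for Cohen's d), with BH-FDR applied
within each statistical map separately over in-brain voxels (a pooled
option exists in config). Conjunctions require same-sign significance in
both maps and display the mean t. Robust second-level regression is
deliberately out of scope.

The JZS Bayes factor integrates the alternative's marginal likelihood over
g ~ inverse-gamma(1/2, 1/2) using the substitution u = g/(1+g), with the
integrand evaluated in log space and shifted by the log-denominator so the
ratio neither overflows at large |t| nor underflows; the e^(−1/(2g))
factor tames the g^(−3/2) endpoint. Adaptive quadrature targets relative
error ≤ 1e−4 (verified at <1% against a 10⁶-draw Monte Carlo oracle). The
BF is computed from the group t (two-stage summary), not per-participant
data. Classification uses thresholds 5 and 1/5 with a strict positive-t
requirement; negative effects never receive a label, and cross-modal
labels demand exact agreement. With N = 90 the BF floor is ≈0.12; note
that at N = 30 the floor rises to ≈0.19, leaving almost no room below the
1/5 null threshold — single-condition ("only") classifications are
therefore nearly unreachable for cohorts much smaller than the reference
N = 90, a structural property of the method worth knowing before applying
it to small studies.

## ROI statistics

Masks: meta-analytic z maps thresholded at z ≥ 3 (inclusive), parcel
unions, or group maps; parcels count as engaged when strictly more than
25% of their voxels are significant. The effect-size bootstrap resamples
participants (the exchangeable unit) with replacement, recomputing both
Cohen's d per sample; p = 2 × proportion of resampled differences at zero
or of sign opposite the observed difference, clamped to [2/n_boot, 1], so
the smallest reportable nonzero p at 10,000 resamples is 2e−4. Fisher z
uses atanh with |r| clipped at 1 − 1e−12 (logged); identical z sets are
reported as no-difference rather than an undefined t. Bonferroni family
sizes are caller-specified and stored with the output.

## Synthetic data generator

The generator emulates the study conditions: two latent group time
courses with target correlation 0.32 on a 230 ms grid; noisy raters with
temporally smoothed errors (mouse-tracking inertia) and first-move delays;
4-rater binary sentence-part annotations with independent label flips;
and BOLD voxels in four classes (both / social_only / tom_only / null)
with exact zero amplitudes for absent effects, AR(1) noise (φ = 0.4),
run-wise drift, motion/CSF-coupled artifacts, and global-signal spike
volumes with matching framewise-displacement bumps.

Latents are smoothed Gaussian processes pushed through the probit squash
x = 100·Φ(z). The squash attenuates a Gaussian correlation ρ to
(6/π)·arcsin(ρ/2), so the pre-squash correlation is set to its inverse,
2·sin(π·r/6), and imposed exactly on the sample by Gram–Schmidt; the
post-squash correlation is then centered on the target (mean within ±0.02
at length 10,000). Rater noise SD defaults to 15 rating units, calibrated
only to keep simulated cohort reliability in a realistic high range (the
reference data report no noise magnitudes). All non-signal BOLD
amplitudes scale with the noise SD, so a noiseless simulation is exactly
linear in the design and OLS recovers planted betas to machine precision —
the anchor for the recovery chain. All randomness flows through one seeded
generator per call; identical seeds give bit-identical output.

What the generator does **not** emulate: spatial structure (voxels are
exchangeable; no smoothing, no spatial autocorrelation, no anatomy),
between-participant amplitude variation that is *spatially correlated*
within regions (between-subject noise is i.i.d. per voxel, which deflates
mask-level variance and inflates mask-level d relative to real data),
realistic linguistic stimuli, scanner physics, or preprocessing artifacts
(data enter post-preprocessing). Passing recovery tests therefore
demonstrate the correctness of the estimators and decision rules, not
robustness to spatially structured noise or registration error.

## Problem sizes and defaults

Pipeline smoke defaults (6 participants, 500 voxels, 2 runs × 160 volumes
per modality, 30 raters) exercise every stage in seconds. The end-to-end
recovery study uses 30 participants × 4000 voxels (1000 per class) × two
modalities of 2 runs × 256 volumes (≈1000 retained timepoints per
participant), planted group d = 1.2 (amplitude 1, between-participant SD
1/1.2), BOLD noise SD 2, outlier rate 1%. Analysis parameters default to
the reference settings throughout: 230 ms grid, TR 0.46 s, 1/128 Hz
high-pass, FDR q = 0.01, BF thresholds 5 and 1/5 at scale √2/2, 2000
split-half permutations, 10,000 bootstrap/surrogate samples. The two
modalities are given independent narrative latents and independent
participant-level effect draws, making modality t statistics conditionally
independent given the voxel class.

## Known limitations

- Trials are identified with runs in the pipeline driver; multi-trial runs
  are supported by the behavior layer but not routed through the driver.
- The BF quadrature is evaluated per voxel (no interpolation cache); maps
  of ~10⁵ voxels take tens of seconds.
- Intermittent (post-trial) ratings, surface-based analysis, cluster-extent
  inference, and robust second-level regression are out of scope.
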