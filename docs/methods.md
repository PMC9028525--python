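# Methods

This note documents the models, parameter choices and numerical
conventions behind the package. It covers the stimulus engine, the
synthetic observer and pattern generator, the classification-image
inference, the behavioral statistics and the RSA model comparison.

## Spatial-frequency decomposition

Images are decomposed into `n_bands` one-octave bands by recursive
low-pass peeling: at each level the current plane is split with a
frequency-domain Gaussian transfer function whose half-amplitude point
sits at the band's lower cut-off, the difference is the band plane, and
the low-pass part seeds the next level. The telescoping sum makes
reconstruction exact to machine precision, which the tests rely on.
Cut-offs are defined on the horizontal axis: the finest band's upper
cut-off is the horizontal Nyquist frequency (`width_px / 2` cycles per
image width, i.e. one cycle per 2 × 2 px), and each subsequent cut-off
halves it. Filters are isotropic in cycles/pixel; for the default
310 × 245 px, 6.90° × 5.47° stimulus the horizontal and vertical
pixels-per-degree differ by under 0.5%, so no anisotropy correction is
applied. For that stimulus the cut-offs are 122.5, 61.25, 30.625,
15.3125, 7.65625 and 3.828125 cycles/image — 22.4 … 0.7 c/deg after
rounding to the display precision.

Bubble standard deviations follow from a fixed number of revealed cycles
per aperture: σ_k = cycles_per_bubble / f_k with f_k the band's upper
cut-off in c/deg (default 3 cycles → 0.13, 0.27, 0.54, 1.07, 2.14 deg,
or 6 to 96 px). Exact values are carried everywhere; rounding happens
only in display.

## Bubble masks and stimulus composition

A mask plane is the sum of unit-peak Gaussians at uniformly random
centers over the full plane (background included), clipped at 1 — the
conventional treatment of overlapping bubbles. Masks are stored as
center coordinates and rendered on demand, so a 2000-trial session costs
a few hundred kilobytes rather than gigabytes.

Composition subtracts the background level (128) before decomposition, so
the stimulus is `background + residual + Σ_k band_k × mask_k`, the
low-pass residual always shown unmasked. With all masks at 1 this
reconstructs the original image exactly; with all masks at 0 it shows the
background merged with the blurred body.

The controller's total bubble count is allocated across bands by a
multinomial draw with weights ∝ 1/σ_k², i.e. equal expected *revealed
area* per band, the standard Bubbles allocation. A uniform split is
unusable at this geometry: coarse-band apertures (σ = 96 px on a
310 × 245 plane) cover ~75% of the image each, so even a handful
saturates the clipped mask plane and destroys the per-pixel variance the
reverse correlation needs.

## Adaptive density controller

Sampling density is adjusted per expression by a multiplicative
staircase: after each trial, `count ← count × (1 + η(target − correct))`
with η = 0.1, target 0.75, clamped to [1, 500]. Correct responses shrink
the count by 2.5%, errors grow it by 7.5%. Note the log-space fixed point
of this rule is at accuracy `log(1.075) / (log(1.075) − log(0.975)) ≈
0.741`, slightly below the nominal 0.75; simulated sessions therefore
settle at ~73–75% correct, inside the ±3-point band used for acceptance.
Each expression's counter is independent, and the update uses
single-trial correctness (the simplest controller consistent with the
design; a running-average variant would change only the settling speed).

## Synthetic bodies and the template observer

Bodies are geometric silhouettes — ellipse head, trapezoid torso flanked
by arm bars, two leg bars — filled at gray 145 on a 128 background, with
±6% per-actor size jitter. The three part masks are mutually disjoint by
construction. Emotional diagnosticity is planted as an
expression-specific texture: vertical (anger) vs horizontal (fear)
6-px-period gratings of amplitude 55 inside a fixed torso-interior box
(intersected with each actor's torso mask), and a 20-px diagonal grating
of amplitude 30 spread over the whole silhouette for neutral (whose
diagnostic mask is therefore spatially diffuse). The gratings are
mutually orthogonal over their shared support, so each expression's
template isolates its own signal.

The observer holds one template per expression — the mean
background-subtracted diagnostic-region content of that expression's
bodies — and responds with the arg-max of (Pearson correlation between
the stimulus and the template over the template's support) plus Gaussian
internal noise, replaced by a uniform guess with probability
`guess_rate`. Accuracy is therefore monotone in the revealed fraction of
the diagnostic region (r grows roughly like the square root of the
revealed energy fraction).

Defaults: `internal_noise_sd = 0.15`, `guess_rate = 0.05`. The noise
default deliberately puts the observer in the *stimulus-limited* regime:
under adaptive sparsification, errors should be driven by missing
diagnostic information (as they are for human observers whose difficulty
is titrated by the mask, not by decision noise). At much higher internal
noise the responses decouple from the revealed content and a
1920-trial reverse correlation is underpowered by construction — the
staircase still converges (the convergence checks use internal noise 0.5
explicitly), but the classification image flattens. This is a property of
the paradigm, not of the implementation, and is worth remembering when
interpreting the recovery tests: they show the pipeline recovers a
planted region from an observer whose errors are information-limited;
they do not show it would do so for an arbitrarily noisy decision stage.

The human decision process is of course not a noisy template matcher;
the observer is a modeling convenience that yields a monotone
psychometric function and a recoverable planted signal, which is all the
downstream pipeline consumes.

## Classification images and cluster inference

Masks are summed separately over correct and error trials per band;
the proportion image is the pixelwise ratio `correct / (correct +
error)`, with never-sampled pixels marked undefined and mean-imputed
before smoothing (they are excluded from nothing else; with 1920 trials
the default geometry samples every pixel). Smoothing uses a σ = 8 px
Gaussian with the plane border padded by the plane mean — padding with
replicated edges inflates border variance and produces spurious corner
maxima after standardization. Each smoothed plane is z-transformed by its
own mean and standard deviation (a zero-variance plane maps to zeros).

Significance uses the Gaussian random-field cluster-extent test:
8-connected clusters of pixels with z > 2.7; the expected cluster count
`E[m]` from the 2-D Euler-characteristic density at the stated FWHM, the
expected supra-threshold area `E[N]` from the Gaussian tail, an
exponential cluster-size law with rate `β = E[m]/E[N]`, and the Poisson
clumping bound `p = 1 − exp(−E[m] e^{−βk})`. Clusters with p ≤ α = 0.05
are reported. Monte-Carlo calibration on stationary unit-variance fields
at FWHM 18.84 px gives a family-wise false-alarm rate of ≈ 0.035–0.04 at
nominal 0.05 — the well-known mild conservatism of the exponential size
approximation at moderate thresholds.

The smoothness passed to the test is taken from the known kernels, not
estimated: for a proportion plane of band k the mask noise is itself
Gaussian-shaped with the band's bubble σ_k, so the effective smoothness
is `FWHM = 2.3548 · sqrt(σ_smooth² + σ_k²)`. For externally supplied
fields the caller passes the appropriate FWHM directly.

Diagnostic summaries: per band, significant pixels divided by the plane
size; per part, pixels of the pooled (any-band) significance mask inside
the part divided by the part's pixel count — pooling keeps the proportion
in [0, 1]. The search region is the full plane, matching the whole-plane
pixel denominators. Classification images are computed per expression;
the recovery analysis pools the two emotional expressions, which share
the planted torso region, doubling the trial count behind the map.

A permutation utility (`shuffle_null_fwer`) re-labels trial correctness
and measures how often the cluster test reports anything on one band's
proportion image; it is both a null-calibration check and the natural
permutation alternative when the Gaussian assumptions are in doubt.

## Behavioral statistics

Wagner's unbiased hit rate `H_u = n_ss² / (row_s · col_s)` (hit rate ×
precision) corrects categorization accuracy for response bias; a
category never chosen scores 0, and H_u equals raw accuracy exactly when
the confusion table is diagonal. Proportions are analyzed untransformed.

The factorial analysis is a repeated-measures ANOVA (one or two within
factors) with Greenhouse–Geisser correction and Bonferroni-adjusted
pairwise contrasts, computed by pingouin behind the module surface and
verified in the tests against hand-computed sums of squares and the
defining epsilon formula. For two within factors with more than two
levels each, the per-effect epsilon is the standard approximation from
the pooled covariance of condition differences (pingouin's convention).
Null simulations (3 × 3 within, n = 15) put the GG-corrected type-I rate
at the nominal 5% within Monte-Carlo error.

## RSA

True RDMs are `1 − r` (Pearson) between condition patterns; group RDMs
are entrywise means. The seven candidate models over the 12-condition
design (3 expressions × 4 part types):

* `body_separate` — each part type its own category (0/1);
* `body_pattern1` — whole body and torso-with-arms merged;
* `emotion_separate` — each expression its own category;
* `emotion_pattern1` — expressions distinguished only among whole-body /
  torso-with-arms conditions; every other pair is maximally dissimilar;
* `body_pattern2` — ranked part-pair tiers: rank 1 for torso↔whole-body
  and torso↔legs, rank 2 for legs↔whole-body, head↔torso and head↔legs,
  rank 3 for whole-body↔head, 0 within a part;
* `emotion_pattern2` — pairs within the whole-body / torso-with-arms
  block carry emotion-refined ranks 0–5 (`2·emotion_tier + part_tier`,
  where emotion tiers are same < anger↔fear < pair-with-neutral and the
  part tier distinguishes same part from whole-body↔torso), the
  torso↔legs tier becomes rank 6, the former rank-2 tier 7 and
  whole-body↔head 8. The exact cellwise layout outside the quoted tiers
  is a documented default, configurable by constructing an `RDM`
  directly; within-part emotion pairs for legs and head stay at 0 as in
  `body_pattern2`;
* `random` — symmetrized uniform noise, seeded (default seed 0).

All candidate models are normalized to [0, 1] by their maximum rank.

Model-data agreement uses Kendall's τ_A over lower-triangle vectors —
ties count in the denominator but never as concordant/discordant, the
appropriate statistic when models predict tied ranks. Relatedness across
subjects is a one-sided Wilcoxon signed-rank test against zero (exact
null for n ≤ 25; an all-zero sample returns p = 1); model pairs use the
two-sided test on paired differences. A one-sample/paired t-test variant
is available (`test="t"`), reflecting a genuine ambiguity in how such
comparisons are reported; the signed-rank default matches what is
typically plotted. FDR control is Benjamini–Hochberg, applied separately
to the 7 relatedness p-values and the 21 pairwise p-values of one ROI,
at q = 0.05 and 0.01 by default.

Summaries for visualization: classical (Torgerson) MDS — double-centered
squared dissimilarities, top two eigen-dimensions, axis signs fixed so
the first condition's coordinates are non-negative — and single-linkage
(nearest-neighbor) agglomeration returned as a SciPy linkage matrix.
The Sørensen–Dice coefficient `2·V_overlap/(V1+V2)` quantifies overlap
between binary maps, defined as 0 when both maps are empty.

## Voxel-pattern simulation

`simulate_patterns` maps a candidate model's rank-normalized
dissimilarities affinely to a target correlation matrix
`R = 1 − signal_scale · D` (an error, with advice to lower
`signal_scale`, if R is not positive semi-definite). Per subject, an
orthonormal column-centered random basis `Q` gives condition patterns
`M = sqrtm(R) Q^T √V`, whose sample correlation matrix is *exactly* R —
so at `noise_sd = 0` the empirical RDM is an exact monotone image of the
generating model. Independent Gaussian noise per voxel then attenuates
expected correlations by `1/(1 + noise_sd²)`, leaving the rank order
intact in expectation. Subjects are independent draws (fresh basis and
noise), making the per-subject τ_A values exchangeable for the
signed-rank inference. Defaults — 20 subjects, 200 voxels,
`signal_scale` 0.5, `noise_sd` 0.5 — give per-subject τ_A values around
0.3–0.7, comparable to well-measured ROI data. The generator works at
the condition-estimate level; it does not emulate fMRI time series,
hemodynamics, spatial voxel correlations or between-subject
heterogeneity of the generating structure, so tests built on it validate
the inference machinery, not robustness to those realities.

## Design arithmetic

Timing calculations use exact rational arithmetic (`fractions.Fraction`)
at every step, so totals at millisecond grain never drift: an
event-related run with the default parameters (6 s lead-in, 108 trials
of mean 4 s fixation + 2 s stimulus, a 10 s rest after every 36th trial)
totals 684 s = 342 volumes at TR 2 s; the block localizer (6 s lead-in,
25 blocks of 1 s fixation + 14 × 1 s image/ISI pairs, a 4 s gap after
every block) totals 481 s — which is 240.5 volumes at TR 2 s. The
half-volume is reported as a fractional count with a warning rather than
reconciled: 481 s and a whole number of 2-s volumes cannot both be
exact, and the module deliberately surfaces that tension instead of
hiding it. Generated fixation jitters are uniform over {2,…,6} s (mean
4 s); expected-duration arithmetic uses the mean.

## Problem sizes in the test suite

The suite runs every pipeline at the scale it is designed for where that
is cheap (full 310 × 245 planes, 1920-trial sessions, 1000 noise fields,
20-subject RSA) and uses reduced Monte-Carlo replicate counts (hundreds
rather than tens of thousands) with correspondingly widened binomial
tolerances for the calibration checks. Property tests are seeded and
deterministic.
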