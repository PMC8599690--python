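# Methods

This note documents the models, numerical conventions and design choices
behind `fearsig`, in the spirit of a statistical-methods appendix.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The signature model

A neural signature is a linear readout of a masked volumetric image: given
in-mask voxel values **x** (fixed flattening order: boolean C-order indexing
of the mask volume), the signature response is ŷ = **W**·**x** + *b*.
Training uses ε-insensitive linear support vector regression with cost
C = 1 (the convention for whole-brain signatures; libsvm via
scikit-learn's `SVR(kernel="linear")`).  Two parameters the convention does
not fix are exposed in config:

- `epsilon` (default 0.1, rating units): the ε-tube of the loss.  Ratings
  stay on their native 1–5 scale.
- `scaling` (default none): optional per-fold feature standardization,
  computed on training data only and folded back into the weights so the
  model always applies to raw images.

Evaluation is subject-wise k-fold cross-validation (default 10 folds — fold
sizes differ by at most one subject — repeated 10 times with fresh random
splits; the per-observation predictions are averaged across repeats before
any metric is computed).  Metrics: overall Pearson r across all
prediction–outcome pairs; within-subject r per subject summarized as
mean ± SE; RMSE; and the explained variance score
EVS = 1 − var(y − ŷ)/var(y) (sample variances; the ddof cancels in the
ratio).  The two-alternative forced-choice test compares two condition
expressions within each subject, crediting ties 0.5, with the binomial SE,
a two-sided binomial test against 50%, and Cohen's d = mean(paired
difference)/SD(paired difference).  Permutation inference shuffles rating
labels within subject and uses the add-one estimator
p = (1 + #{stat ≥ obs})/(1 + n), which is valid (conservative) by
construction.

## Synthetic cohorts

The generator is the package's study design, not a tuning dial; its defaults
were fixed once from the regime the method is meant for and are the
conditions under which all recovery and calibration tests run.

**Lattice.**  24×24×18 voxels (2 mm), ellipsoidal mask of ~4,000 voxels —
large enough for true 3-D sphere geometry, small enough for desk-scale
searchlights.  A 5×3×2 grid of 30 contiguous box parcels is labeled with the
seven canonical resting-state network names plus a central "subcortical"
group; a "consciousness" composite spans the frontoparietal and default
parcels plus one ventral-attention parcel.  Tests use a 12×12×10 version
(~520 voxels) of the same construction.

**Ground truth.**  The encoding pattern occupies one parcel in each of three
networks (default, frontoparietal, subcortical), with unit L2 norm, so the
representation is genuinely distributed and no single network suffices.  A
threat pattern lives in visual parcels and is exactly orthogonalized against
the encoding pattern (residual cosine < 1e−10).  A suppressor pattern
bridges a signal parcel and a quiet parcel: it injects shared noise with
zero outcome signal, making the forward-model (Haufe) analysis non-trivial.

**Trial model.**  The map of subject *s*, trial *t* with rating *r* is
r·effect_size·encoding + subject_effect(s) + z_t·suppressor_sd·suppressor
+ white noise.  Defaults: effect_size = 1.0 per rating unit,
sigma_within = 2.5, sigma_between = 0.8, suppressor_sd = 1.0 (all per-voxel
SDs; because the encoding pattern has unit norm these are also the SDs along
the signature direction).  The within-trial value was chosen so that
condition-level maps — within-subject means of the 12–16 trials sharing a
rating — have a projected noise SD near 0.7 against a rating signal SD near
1.4, i.e. the within-subject condition-level prediction regime (r ≈ 0.9)
reported for empirical fear signatures.  Ratings come from a discretized
latent intensity with equal-width thresholds; the default uniform latent
yields approximately balanced level frequencies, and a `latent="normal"`
mode yields bell-shaped frequencies.  A configurable number of subjects
(default 2 of 67) never report the top level, reproducing the 333-pair
condition-map count (65×5 + 2×4).

**Time series.**  Voxel time courses are Σ_trials amplitude_map ⊗
(boxcar ⋆ HRF) + cosine drift + AR(1) noise (stationary marginal SD), with
amplitude maps drawn from the trial model.  The same convolution code
serves generation and GLM fitting, so the noiseless single-trial recovery
test is exact by construction; what it verifies is the design/estimation
algebra, not convolution round-off.

**What the generator does *not* emulate:** hemodynamic nonlinearity and
variability, physiological noise, motion, spatial autocorrelation of
scanner noise, registration error, and real anatomy.  Passing tests
therefore demonstrate correctness and calibration of the *methods* under a
known generating model — not performance claims about real fMRI data.

## First-level GLMs

The canonical HRF is the standard double-gamma (peak delay 6 s, undershoot
delay 16 s, unit dispersions, peak:undershoot ratio 6, 32-s support, unit
peak).  Convolution happens at 16 microtime bins per TR with slice-reference
bin 1.  High-pass filtering is a DCT basis inside the design (cutoff 128 s,
order floor(2T/cutoff)), keeping OLS exact rather than pre-filtering.  Six
motion inputs expand to 24 nuisance columns (parameters, squares, backward
derivatives, squared derivatives).  The parametric modulator is the
mean-centered rating times the picture boxcar; orthogonalization against the
main regressor is off by default (toggle provided).  Rank-deficient designs
raise an error naming the collinear columns.

Single-trial estimation supports LSA (one GLM, one regressor per trial) and
LSS (per-trial GLM with a target-vs-all-others design).  Trial VIFs are
computed on the LSA design in both modes — QC is a property of the joint
trial layout — against **all** other non-intercept columns (task, nuisance,
drift): trial-vs-trial collinearity is the dominant failure mode, with
nuisance collinearity included.  VIF = 1/(1 − R²), +inf at exact
collinearity, exclusion threshold 3.  LSA refuses designs with more columns
than scans and points to LSS.  Note that LSA and LSS coincide only in the
orthogonal limit; with unequal trial amplitudes and shared drift/intercept
columns they differ, shrinking as trials separate.

## Interpretation

The Haufe transform converts decoder weights into an activation pattern
A = cov(X)·W / var(S), S = X·W (the single-latent-factor case, so cov(S) is
scalar).  Covariances use mean-centered sample (n−1) normalization on the
training data.  A voxel used purely to cancel shared noise keeps its decoder
weight but gets A ≈ 0, which is why anatomical claims require both maps.

Bootstrap weight maps resample **subjects** with replacement (the natural
exchangeable unit; resamples with constant ratings are redrawn), retrain
with the full-data configuration, and summarize per-voxel Z = mean/SD with
two-tailed normal p values.  These Z maps are a reliability summary, not an
exactly calibrated per-voxel test — under a complete null their uncorrected
p values are mildly anticonservative, but after BH-FDR at q < 0.05 the
significant-voxel proportion stays below 5% (verified by the 200-simulation
calibration test).  Group t maps set t = 0, p = 1 and flag voxels with zero
across-subject variance rather than emitting infinities.  Idiographic
models fit one SVR per subject on trial data with trial-fold CV; the
significance inclusion filter is available but off by default (group maps
include everyone).

## Regional analyses

Searchlight spheres use integer offsets within the Euclidean radius
(default 3 voxels, center included); each sphere runs the identical
subject-wise CV, and significance defaults to the analytic p of the overall
prediction–outcome correlation (a permutation option exists but is costly).
Parcel and network/composite restrictions re-run the same CV on the voxel
subset; restricting to the full mask reproduces the whole-mask run
bit-for-bit at a fixed scheme seed, which pins the implementation.

Sampling curves draw k voxels without replacement from a region set,
run the restricted CV, and average over iterations; each curve is anchored
at the full region size so the plateau is observed, then fit with
r(k) = r∞·(1 − e^(−k/τ)) by bounded least squares.  The saturating
exponential is a pragmatic choice for a monotone saturating mean curve, not
a mechanistic claim, and is swappable; with fewer than four grid points the
fit is unidentified and the asymptote falls back to the observed
full-region mean.  Reduced desk-scale defaults (n_iter = 50 down from 1000;
bootstrap/permutation counts configurable down from 10,000) are used
throughout the tests; the acceptance suite pins the reduced values it runs.

## Specificity

Cross-classification applies any signature to a two-condition set
(within-subject forced choice; inference by within-subject sign
permutation).  Spatial correlation between weight maps uses a one-tailed
permutation p with two null schemes: voxel shuffle (default) and a
parcel-block null implemented as independent random sign flips of whole
parcels — a block scheme that preserves within-parcel structure and
produces the appropriately wider null on spatially smooth maps.  Neither
scheme is claimed canonical; both ship.

The octant analysis z-scores both weight maps across voxels, places map 1 on
the y axis and map 2 on the x axis, and divides the plane into eight 45°
sectors with boundaries at 22.5° + k·45°: sector 1 centered on +y, numbered
clockwise (2 = shared-positive diagonal, 3 = +x, 4 = x+/y−, 5 = −y,
6 = shared-negative diagonal, 7 = −x, 8 = x−/y+).  This is the unique
8-sector scheme in which the axes mean "selective" and the diagonals mean
"shared"/"opposite".  SSDO (sum of squared distances from the origin) is
accumulated per sector; voxels exactly at the origin are excluded and
counted.

## Multilevel mediation

First level: per-subject OLS of a (M~X), c (Y~X), and jointly (c′, b)
(Y~X+M); the identity c − c′ = a·b is exact for a single mediator and is
asserted on every fit.  Second level: unweighted subject-mean random
effects; a precision-weighted option (weights ∝ inverse squared first-level
SEs) is provided because hierarchical toolboxes weight by first-level
precision — the unweighted mean is the documented default, chosen for
transparency.  Inference resamples subjects with replacement; per-path
intervals are BCa (bias z₀ from the fraction of draws below the estimate,
acceleration â from the jackknife skewness formula), and the two-sided p
inverts the BCa mapping at the null value.  BCa reduces exactly to the
percentile interval when z₀ = 0 and â = 0.  Both mediation directions (X
and M swapped) can be run side by side.

## Problem sizes and determinism

Simulation studies in the test and acceptance suites run at sizes chosen to
make each property measurable with stable margins at desk scale: the ~520
voxel lattice for anything requiring many retrainings; 100 replicates for
chance-level studies; 200 simulations × 500–600 resamples for permutation,
bootstrap and mediation calibration; 100 simulations of 32 subjects × 80
trials for the distributed-representation comparison; 12 iterations per
grid point for sampling curves.  Recovery bounds asserted by the acceptance
tests (overall CV r > 0.45, weight-pattern cosine > 0.45, trial-wise
within-subject r in [0.15, 0.45]) were pinned from a pilot run at the
frozen seeds before the tests were frozen.  Every stochastic routine takes
an explicit seed and draws from its own `numpy.random.Generator`; no global
state is used, identical configs reproduce outputs bit-for-bit, and the
pipeline driver stamps every artifact with the config hash, seed and mask
fingerprint.

## Known limitations

- The SVR weight solution matches the algorithmic convention (libsvm) but
  not any particular historical toolbox's numerics; exact weight equality
  with other implementations is not a goal.
- Bootstrap Z maps are anticonservative voxel-wise before FDR (see above).
- The searchlight's analytic p ignores the dependence induced by
  cross-validation folds; treat searchlight significance as descriptive or
  use the permutation option.
- No AR(1) prewhitening in the GLM (the generator's AR noise is handled by
  OLS consistency, not efficiency); no robust regression; no cluster-extent
  or TFCE inference; no surface projection; no real atlases (real-atlas
  NIfTI inputs are accepted but not shipped).
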