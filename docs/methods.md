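# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the toolkit, in the order the data flow through it.

## Preprocessing chain

Stages run in a fixed order on each raw spectrum:
despike (optional) → blank subtraction → wavelet denoising → polynomial
fluorescence removal → rubberband anchoring → vector normalization.
The chain is deterministic: identical inputs and configuration give
bit-identical outputs. It is *not* idempotent — a second pass refits the
polynomial baseline on an already-flattened spectrum and changes values.

**Blank subtraction.** The mean of the supplied blank (substrate) spectra,
resampled onto the spectrum's axis, is subtracted. The mean is the
minimal-variance combination of replicate blanks. Negative values are
permitted at this stage; later stages handle them.

**Wavelet denoising.** Multi-level Haar decomposition (default 6 levels);
detail coefficients at every level are soft-thresholded at the universal
threshold `σ·√(2 ln N)`. σ is the median absolute deviation *about the
median* of the level-1 detail coefficients, divided by 0.6745. Centering
on the median (rather than on zero) makes σ exactly zero for a noise-free
linear trend, so smooth signals pass through untouched; for zero-mean
Gaussian noise the two estimators coincide. Known limitation: the
universal threshold is aggressive — narrow bands whose detail
coefficients are comparable to the threshold are attenuated by an amount
that depends on their alignment with the dyadic grid. With detector noise
at a few percent of the strong-band amplitude this is negligible; at ≥5%
noise, marker bands with ≤25% of the backbone amplitude can lose half
their height or vanish.

**Polynomial fluorescence removal.** A least-squares polynomial (default
order 5) is fit to the spectrum and iteratively refit on the points at or
below the current fit (up to 100 passes or until the support set is
stable), so the fit tracks the broad fluorescence under narrow Raman
peaks. The subtracted baseline is kept as the autofluorescence signal: it
has the same variable count as the Raman fingerprint and can be fused with
it downstream. Raman + fluorescence reconstructs the input exactly.

**Rubberband anchoring.** The lower convex hull of (wavenumber, intensity)
is computed by monotone chain; the piecewise-linear baseline through the
hull points is subtracted. The result is non-negative and exactly zero at
both spectrum ends (the hull always contains both endpoints).

**Vector normalization.** Unit Euclidean norm per spectrum. Scale-invariant
and idempotent; an all-zero spectrum is a hard error.

**Despiking** (default off) replaces, within each sample's repeat
acquisitions, points more than 5 MADs above the per-column median with the
median — an automated substitute for manual cosmic-ray removal.

**Standardization** (per-variable zero mean, unit sample SD) is a separate
step applied immediately before PCA; zero-variance columns become zeros
with a logged warning.

## Multi-excitation fusion

MX spectra are built by end-on-end concatenation of per-channel
fingerprints: each output row concatenates one spectrum per channel from
the same sample, paired by acquisition index (a by-rank fallback covers
channels whose acquisition numbering differs). No joint renormalization is
applied: each block keeps its own unit norm, and block values are
preserved bit-exactly. The total variable count is always the exact sum of
the block sizes — concatenating two 1013-variable fingerprints gives
2026 variables, and the toolkit never trims to any other number. Repeated
channel tags (self-concatenation) are suffixed (`532nm#2`) so every output
column maps back to a unique (channel, wavenumber) pair.

Depolarization spectra are element-wise ρ = I⊥ / max(I∥, floor) on paired
polarized datasets sharing one axis; the floor defaults to 10⁻⁶ of the
parallel dataset's maximum and floored entries are counted in the log
(ρ < 0.75 marks a totally symmetric vibration). Raman-autofluorescence
fusion vector-normalizes the fluorescence block before concatenation and
tags it `fluor-<channel>`.

## Spectral barcoding

**Per-wavenumber ranking.** Two-sided Mann-Whitney U per variable between
two classes. Small groups (both ≤ 20) use the exact null: scipy's exact
method for untied columns, and a tie-aware exact permutation enumeration
(all C(n₁+n₂, n₁) assignments of the pooled midranks, doubling the smaller
tail) whenever at most 200 000 assignments exist. Larger groups use the
normal approximation with tie correction. Variables are ranked by p-value,
ties broken by larger absolute median difference, then lower column index;
the direction flag is the sign of the (class b − class a) median
difference (+1 = increase/"black", −1 = decrease/"gray"), matching the
nonparametric test (medians, not means).

**Disease barcodes.** One control-vs-disease test; a *spectral region* is
a maximal unbroken run of variables with p < α (default 0.05, uncorrected)
that never crosses a channel-block boundary. Regions are seeded, in rank
order, by the best-ranked significant variables not already inside a
chosen region; the three chosen regions are therefore pairwise disjoint,
and every variable of each region enters the barcode. The α-mask run rule
is the minimal operationalization of "an unbroken sequence of variables";
α is configurable.

**Universal barcodes.** All k(k−1)/2 pairwise tests (10 for 5 classes).
Per test the top-10 variables are taken; sizes are then built as:
`full` — all variables ordered by best pairwise p; `half` — the top half
of that ordering; `100` — union of per-test top-10 sets; `30` — per test,
the top-10 are reduced to 3 by mRMR; `10` — each test's single top mRMR
variable. Unions are deduplicated and deterministically backfilled
(round-robin over the tests' next-ranked candidates) so the stated sizes
are exact. Directions come from the test that contributed each variable.

**mRMR.** Greedy difference criterion: the first pick maximizes mutual
information with the class label; subsequent picks maximize relevance
minus mean mutual information with the already-selected set. Variables are
discretized into deciles over the dataset; ties break to the lower column
index, making selection fully deterministic.

**Negative control.** One-way ANOVA F per variable across all classes; the
k variables with the largest p-values (constant columns get p = 1, logged)
form the lowest-rank barcode — variables demonstrably *not* descriptive of
class.

A structural property worth knowing: when group sizes are large and a
marker band separates classes completely, every column in the band's
neighborhood saturates the test, so a pair's top-10 tends to lie inside
the single strongest band (the neighborhood spans ~1.5× FWHM on each
side). The per-test mRMR step then diversifies *within* that band only.
Consequently the number of distinct marker locations a 30-variable
universal barcode can cover is bounded by the number of pairwise tests,
and the bound tightens as spectral resolution grows (the top-10 is a fixed
count, not a fixed wavenumber window).

## Cluster metrics

Evaluation pipeline: apply barcode (optional) → standardize → PCA
(3 components, deterministic sign convention: each loading's
largest-magnitude element is positive) → optionally LDA → metrics.

**PCA-LDA.** LDA is fit on the first max(k−1, 3) PC scores so that its
full k−1 discriminants exist (4 LDs for 5 classes); the first 3 LDs are
retained. This matters: Bhattacharyya distance is invariant under
invertible affine maps, so LDA from 3 PCs to 3 LDs would provably leave
the metric unchanged; retaining 3 of 4 discriminants is a genuine
projection.

**Bhattacharyya distance.** Gaussian form with sample means and
covariances, computed in the retained 3-component space (configurable).
Near-singular covariances get a ridge `ε·I`, ε = 10⁻⁸·trace/dim (logged).
Symmetric, zero for identical clouds, affine-invariant (verified to 10⁻⁶
in tests); for two equal-variance 1-D Gaussians it converges to Δ²/(8σ²).
The average over all class pairs is the headline separation figure.

**Mahalanobis spread.** For each class, the mean distance of its points to
the class centroid in the PC1–PC2 plane, normalized by default by the
sample covariance of *all* scores ("total"): the distance to the cluster
center is measured against the data ellipsoid's width in that direction,
so the statistic falls when intraclass variance shrinks relative to the
retained between-class structure — the behavior a feature-selection
comparison needs. A `per_class` variant normalizes each class by its own
covariance; that version is invariant under any affine transform of the
class's points, hence measures only cluster *shape* (heavy tails,
multimodality) and cannot register tightening — it is provided for shape
diagnostics, not for barcode comparisons.

## Supervised evaluation protocol

**Splits.** Every sample contributes the same number m of spectra; repeat
r ∈ {1,2,3} takes each sample's acquisitions at positions {0,1,2},
{m/2−1, m/2, m/2+1}, {m−3, m−2, m−1} (0-based, by acquisition order) as
test and the rest as train — 405 train / 45 test per repeat at 15 samples
× 30 spectra. Because each sample appears in both partitions, accuracies
are optimistic: every report carries the note that results support
*configuration comparison, not predictive validation*.

**LDA.** Pooled within-class covariance Gaussian discriminant. The pooled
covariance is inverted through a thin SVD of the within-class-centered
matrix; singular directions are dropped at numpy's pinv tolerance, so the
classifier is the Moore-Penrose pseudo-inverse ("pseudo-linear") LDA when
variables outnumber training spectra, and reduces exactly to classical LDA
on full-rank problems (verified against scikit-learn's SVD solver).
Training reports stratified 5-fold cross-validation accuracy per class;
fold assignment is seeded and recorded. Duplicating the feature block
(self-concatenation) provably leaves predictions unchanged, which the
evaluation reproduces empirically.

**Comparison.** Each configuration yields k classes × 3 repeats class-level
test accuracies (15 values for 5 classes), summarized as mean ± SD.
Configurations are compared with the Kruskal-Wallis omnibus test followed
by Dunn-style pairwise rank z-tests with tie correction and Bonferroni
multiplication (capped at 1). All-identical inputs give H = 0, p = 1 by
convention.

## Synthetic data generator

Each raw spectrum is a sum of Lorentzian bands + baseline + noise:

- **Backbone:** 12 shared bands (747–1660 cm⁻¹) whose per-channel
  amplitudes differ, emulating resonance/preresonance enhancement of a
  subset of modes in the shorter-wavelength channel.
- **Class markers:** the two single-channel disease classes carry three
  equal-amplitude bands (0.45 of unit scale) confined to one channel, at
  centers distinct from the backbone and away from the axis edges — the
  structure the three-region disease barcode is designed to find. The two
  "hard" classes share their two marker centers but with swapped
  cross-channel amplitude ratios (0.25/0.16), so only the *relative*
  channel intensities distinguish them: by construction they are the
  hardest pair, confusable mostly with each other.
- **Variability:** lognormal multiplicative amplitude effects per
  (sample, band) with σ = 0.08 (patient-to-patient variability under a
  standardized preparation protocol) and per (spectrum, band) with
  σ = 0.08 — the spot-to-spot compositional heterogeneity of a dried
  droplet, where each acquisition probes a different location. The
  spectrum-level term matters statistically: without it, sample-level
  offsets make *any* variable separate classes perfectly given enough
  spectra per sample (pseudoreplication), which real droplet data do not
  show.
- **Baseline:** a fixed broad shape (gentle tilt + wide Gaussian hump)
  scaled by 5× the peak scale, with per-spectrum lognormal scale jitter
  (σ = 0.1); blanks are baseline + noise only, three per channel.
- **Noise:** additive white Gaussian, σ = 0.02 of unit band scale —
  high-SNR averaged acquisitions. This interacts with the denoising
  threshold (see above): at substantially higher noise the prescribed
  universal-threshold denoising erases the weaker marker bands.
- **Axes:** 600–1750 cm⁻¹ per channel, 1024 points by default
  (wavelet-friendly, ~1.1 cm⁻¹ spacing).

The ground-truth record lists, per class, each planted band's channel,
center column and ±FWHM window with its expected direction (+1; class
bands only add intensity). Generation is fully deterministic per seed.

What the generator does *not* emulate: physically calibrated Raman
cross-sections, instrument response and wavelength-dependent throughput,
cosmic rays, detector saturation, wavenumber calibration drift between
acquisitions, and correlated (structured) noise. Passing recovery tests
on this generator therefore demonstrates that the selection machinery
finds class structure of the assumed form at realistic noise levels — not
that any particular instrument or tissue preparation will yield such
structure.

## Problem sizes used in the test and acceptance runs

The structural and recovery checks run the reference study shape
(5 classes × 3 samples × 30 spectra = 450 per channel) on 512-point axes;
the 20-seed configuration comparisons use a reduced study (12 spectra per
sample, 256-point axes) whose class structure is identical. These sizes
are the package's own choice of desk-scale defaults; all counts that the
protocol fixes (450 spectra, 405/45 splits, barcode sizes 30 and 10, 10
pairwise tests) are invariant to them.

## Known limitations

- The positional split scheme deliberately reuses samples across train
  and test; none of the reported accuracies are estimates of out-of-sample
  diagnostic performance. Patient-level validation (leave-one-subject-out)
  is out of scope here and the natural next step.
- Exact U tests are limited to small groups; large-group p-values rely on
  the normal approximation with tie correction.
- The universal-threshold wavelet denoiser trades weak-band fidelity for
  noise suppression; with noisy data consider `wavelet_levels` or
  normalization choices carefully.
- mRMR uses decile binning; with fewer than ~20 spectra the MI estimates
  are coarse.
- The fixed top-10-per-test rule makes universal barcodes
  resolution-sensitive: at finer spectral sampling a single band's
  neighborhood fills the top-10, capping how many distinct marker
  locations small barcodes can cover.
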