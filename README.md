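# mxraman

A chemometrics toolkit for **multi-excitation (MX) Raman spectral
barcoding**: label-free fingerprinting and classification of complex
biological samples (tissue fractions, biofluids) measured at several laser
excitation wavelengths and polarization states.

Raman spectra of complex mixtures are high-dimensional, strongly
correlated, and dominated by variance unrelated to the question being
asked. This toolkit implements a complete workflow for squeezing class
information out of them:

1. **Preprocessing** — blank (substrate) subtraction, 6-level Haar wavelet
   denoising (soft universal threshold), 5th-order polynomial
   autofluorescence removal with the fitted baseline retained as a signal
   in its own right, rubberband (lower convex hull) anchoring, and vector
   normalization.
2. **Multi-excitation fusion** — end-on-end concatenation of per-channel
   fingerprints into MX spectra (e.g. 532 nm + 785 nm), Raman +
   autofluorescence fusion, and depolarization-ratio spectra
   ρ = I⊥/I∥ from polarized acquisitions.
3. **Spectral barcoding** — per-wavenumber two-sided Mann-Whitney U tests
   between classes; disease-specific barcodes built from the three
   top-ranked *independent* significant spectral regions; universal
   multi-class barcodes of exact sizes (half / 100 / 30 / 10 variables)
   via greedy minimum-redundancy maximum-relevance (mRMR) reduction of
   per-test top-10 variables; an ANOVA lowest-rank negative control.
4. **Evaluation** — unsupervised cluster structure (per-class Mahalanobis
   spread in PC1–PC2, pairwise Gaussian Bhattacharyya distances in
   PCA or PCA-LDA space) and a supervised configuration-comparison
   protocol: positional train/test splits (first / middle / final 3
   acquisitions of each sample), pooled-covariance LDA with stratified
   5-fold cross-validation (Moore-Penrose pseudo-inverse when variables
   outnumber training spectra), per-class accuracies, and
   Kruskal-Wallis + Bonferroni comparison between configurations.
5. **Synthetic data** — a generator for multi-channel Raman-like studies
   (Lorentzian peaks, channel-specific resonance-like enhancement,
   patient- and spot-level lognormal amplitude effects, broad fluorescence
   baselines, detector noise) with a ground-truth record of every planted
   class marker, so the whole workflow is testable end to end.

The statistics at the core:

- Mann-Whitney U per wavenumber, exact null for small groups (tie-aware
  permutation enumeration when ties are present), normal approximation
  with tie correction otherwise.
- mRMR (difference criterion): greedily maximize I(X; class) − mean
  I(X; selected), with decile-discretized mutual information.
- Bhattacharyya distance between class clusters
  `D_B = ⅛ (μ₁−μ₂)ᵀ Σ̄⁻¹ (μ₁−μ₂) + ½ ln[det Σ̄ / √(det Σ₁ det Σ₂)]`,
  Σ̄ = (Σ₁+Σ₂)/2.
- Mahalanobis spread: mean distance of a class's points to its centroid,
  normalized by the whole-data ellipsoid in the PC1–PC2 plane.

## Worked example

A reduced synthetic study (5 classes × 3 samples × 12 spectra per sample,
two channels of 256 points) run entirely in memory:

```python
import mxraman as mx

design = mx.paper_like_design(n_points=256, n_spectra_per_sample=12)
res = mx.generate(design, seed=1)

fp532, _ = mx.run_pipeline(res.channels["532nm"], res.blanks["532nm"])
fp785, _ = mx.run_pipeline(res.channels["785nm"], res.blanks["785nm"])
mxset = mx.concatenate([fp532, fp785])          # 512-variable MX spectra

report = mx.run_protocol(
    {"532": fp532, "785": fp785, "MX": mxset.dataset}, seed=1
)
for name in ("532", "785", "MX"):
    rec = report.per_config[name]
    print(f"{name}: {rec['mean']:.1f}% +- {rec['sd']:.1f}%")

b30 = mx.universal_barcode(mxset.dataset, 30)   # 30-variable barcode
sep_full = mx.separation_report(mxset.dataset)
sep_b30 = mx.separation_report(mxset.dataset, b=b30)
print(f"avg Bhattacharyya, full spectrum: {sep_full.average_bhattacharyya:.2f}")
print(f"avg Bhattacharyya, 30-variable barcode: {sep_b30.average_bhattacharyya:.2f}")
```

prints

```
532: 56.3% +- 23.6%
785: 51.1% +- 26.8%
MX: 95.6% +- 7.0%
avg Bhattacharyya, full spectrum: 0.65
avg Bhattacharyya, 30-variable barcode: 10.37
```

Each single channel resolves only part of the class structure (class A
differs only at 532 nm, class B only at 785 nm), so fusing the two
channels lifts the mean test accuracy from ~51–56% to ~96% — the
accuracy values are class × repeat means from the positional-split
protocol, which is a *configuration comparison*, not predictive
validation (test spectra share samples with training spectra). Reducing
the 512 MX variables to the 30-variable barcode raises the average
between-class Bhattacharyya distance ~16-fold: almost all of the
discarded variance was noise or class-unrelated.

The same workflow is scriptable from a shell:

```sh
mxraman simulate --out-dir sim/ --seed 7
mxraman preprocess --in sim/raw_532nm.csv --blanks sim/blanks_532nm.csv --out fp532.csv
mxraman preprocess --in sim/raw_785nm.csv --blanks sim/blanks_785nm.csv --out fp785.csv
mxraman combine --inputs fp532.csv --inputs fp785.csv --out mx.csv
mxraman barcode --in mx.csv --mode universal --size 30 --out b30.json
mxraman metrics --in mx.csv --barcode b30.json --out metrics.json
mxraman classify --configs fp532.csv --configs fp785.csv --configs mx.csv \
    --names 532 --names 785 --names MX --seed 7 --out report.json
```

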