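"""Spectral preprocessing chain for Raman fingerprints.

The chain applied by :func:`run_pipeline` mirrors standard chemometric
practice for dried-droplet Raman measurements, in this order:

1. optional despiking (median across a sample's repeat acquisitions),
2. blank (substrate) background subtraction,
3. Haar wavelet denoising (6 decomposition levels by default, soft
   universal threshold, noise sigma from level-1 detail coefficients),
4. polynomial autofluorescence removal (5th order by default, iterative
   peak-exclusion refit; the fitted baseline is retained as the
   autofluorescence signal),
5. rubberband anchoring (lower convex-hull baseline, ends pinned to zero),
6. vector normalization (unit Euclidean norm).

Per-variable standardization (:func:`standardize_columns`) is a separate
step applied immediately before PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import (
    DegenerateInputError,
    InvalidConfigError,
    InvalidInputError,
    MissingBlankError,
)
from .spectral_io import SpectralDataset, Spectrum, resample_to_axis

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain."""

    wavelet_levels: int = 6
    poly_order: int = 5
    normalize: str = "vector"  # "vector" | "none"
    standardize_for_pca: bool = False
    despike: str = "off"  # "off" | "multi_acquisition_median"

    def validate(self, n_variables: int) -> None:
        if self.wavelet_levels < 1:
            raise InvalidConfigError("wavelet_levels must be >= 1")
        if n_variables < 2**self.wavelet_levels:
            raise InvalidConfigError(
                f"signal of length {n_variables} too short for "
                f"{self.wavelet_levels} wavelet levels"
            )
        if self.poly_order < 0 or self.poly_order >= n_variables:
            raise InvalidConfigError("poly_order must satisfy 0 <= order < n points")
        if self.normalize not in ("vector", "none"):
            raise InvalidConfigError(f"unknown normalize mode {self.normalize!r}")
        if self.despike not in ("off", "multi_acquisition_median"):
            raise InvalidConfigError(f"unknown despike mode {self.despike!r}")


# ---------------------------------------------------------------------------
# single-spectrum stages (array kernels + Spectrum wrappers)
# ---------------------------------------------------------------------------

def subtract_background(s: Spectrum, blanks: list[Spectrum]) -> Spectrum:
    """Subtract the mean of the blank (substrate) spectra from ``s``.

    Blanks are resampled onto ``s.axis`` first; negative values in the result
    are permitted (later baseline stages handle them).
    """
    if not blanks:
        raise MissingBlankError("no blank spectra supplied")
    stack = np.vstack(
        [resample_to_axis(b, s.axis).intensities for b in blanks]
    )
    return s.with_values(s.intensities - stack.mean(axis=0))


def _denoise(y: np.ndarray, levels: int) -> np.ndarray:
    if y.size < 2**levels:
        raise InvalidConfigError(
            f"signal of length {y.size} too short for {levels} wavelet levels"
        )
    coeffs = pywt.wavedec(y, "haar", level=levels)
    detail1 = coeffs[-1]
    # MAD about the median: zero for noise-free (linear-trend) detail bands,
    # ~ sigma for Gaussian noise, so smooth signals pass through untouched
    sigma = np.median(np.abs(detail1 - np.median(detail1))) / 0.6745
    threshold = sigma * np.sqrt(2.0 * np.log(y.size))
    if threshold > 0:
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode="soft") for c in coeffs[1:]
        ]
    return pywt.waverec(coeffs, "haar")[: y.size]


def wavelet_denoise(s: Spectrum, levels: int = 6) -> Spectrum:
    """Multi-level Haar denoising with the soft universal threshold.

    Noise sigma is the median absolute level-1 detail coefficient divided by
    0.6745; details at every level are soft-thresholded at
    ``sigma * sqrt(2 ln N)`` before reconstruction.
    """
    return s.with_values(_denoise(s.intensities, levels))


def _poly_baseline(
    x: np.ndarray, y: np.ndarray, order: int, max_iter: int = 100
) -> np.ndarray:
    """Iteratively refit polynomial baseline, excluding points above the fit."""
    if order >= y.size:
        raise InvalidConfigError("poly_order must be < number of points")
    scale = np.max(np.abs(y)) if y.size else 0.0
    tol = 1e-12 * max(scale, 1.0)
    support = np.ones(y.size, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(max_iter):
        series = np.polynomial.Polynomial.fit(x[support], y[support], order)
        fit = series(x)
        new_support = y <= fit + tol
        if new_support.sum() <= order + 1 or np.array_equal(new_support, support):
            break
        support = new_support
    return fit


def remove_fluorescence(
    s: Spectrum, order: int = 5, max_iter: int = 100
) -> tuple[Spectrum, Spectrum]:
    """Split a spectrum into (Raman, autofluorescence baseline) parts.

    A least-squares polynomial of the given order is fit to the spectrum and
    iteratively refit on the points at or below the current fit (up to
    ``max_iter`` passes or until the support set stabilizes), so the fit
    tracks the broad fluorescence under narrow Raman peaks.  Returns
    ``(s - fit, fit)``; the two parts sum back to the input exactly.
    """
    fit = _poly_baseline(s.axis, s.intensities, order, max_iter=max_iter)
    raman = s.with_values(s.intensities - fit)
    fluor = s.with_values(fit)
    fluor.signal_kind = "autofluorescence"
    return raman, fluor


def _lower_hull_baseline(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    hull_idx = [0]
    for i in range(1, x.size):
        while len(hull_idx) >= 2:
            o, a = hull_idx[-2], hull_idx[-1]
            cross = (x[a] - x[o]) * (y[i] - y[o]) - (y[a] - y[o]) * (x[i] - x[o])
            if cross <= 0:
                hull_idx.pop()
            else:
                break
        hull_idx.append(i)
    return np.interp(x, x[hull_idx], y[hull_idx])


def rubberband_anchor(s: Spectrum) -> Spectrum:
    """Subtract the lower convex-hull baseline, anchoring both ends to zero.

    The baseline is the piecewise-linear curve through the lower convex hull
    of (axis, intensity) points; the result is non-negative everywhere and
    exactly zero at the first and last point.
    """
    if s.axis.size < 3:
        raise InvalidInputError("rubberband anchoring needs at least 3 points")
    baseline = _lower_hull_baseline(s.axis, s.intensities)
    out = np.maximum(s.intensities - baseline, 0.0)
    out[0] = 0.0
    out[-1] = 0.0
    return s.with_values(out)


def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities to unit Euclidean norm."""
    norm = np.linalg.norm(s.intensities)
    if norm == 0.0:
        raise DegenerateInputError("cannot vector-normalize an all-zero spectrum")
    return s.with_values(s.intensities / norm)


# ---------------------------------------------------------------------------
# dataset-level stages
# ---------------------------------------------------------------------------

def standardize_columns(d: SpectralDataset) -> SpectralDataset:
    """Center each column and scale to unit sample standard deviation.

    Zero-variance columns are set to zero (with a logged warning) rather
    than producing NaNs.
    """
    if d.n_spectra < 2:
        raise InvalidInputError("standardization needs at least 2 rows")
    mean = d.matrix.mean(axis=0)
    sd = d.matrix.std(axis=0, ddof=1)
    constant = sd == 0.0
    if constant.any():
        logger.warning(
            "standardize_columns: %d zero-variance column(s) set to 0",
            int(constant.sum()),
        )
    safe_sd = np.where(constant, 1.0, sd)
    out = d.copy()
    out.matrix = (d.matrix - mean) / safe_sd
    out.matrix[:, constant] = 0.0
    return out


def despike_median(d: SpectralDataset, n_mads: float = 5.0) -> SpectralDataset:
    """Replace cosmic-ray-like outliers using a sample's repeat acquisitions.

    Within each sample, points more than ``n_mads`` median absolute
    deviations above the per-column median over that sample's acquisitions
    are replaced by the median.
    """
    out = d.copy()
    for _, idx in out.row_meta.groupby("sample_id").groups.items():
        rows = out.matrix[np.asarray(idx)]
        med = np.median(rows, axis=0)
        mad = np.median(np.abs(rows - med), axis=0)
        mask = (rows > med + n_mads * mad) & (mad > 0)
        if mask.any():
            rows = np.where(mask, med, rows)
            out.matrix[np.asarray(idx)] = rows
    return out


def run_pipeline(
    d: SpectralDataset,
    blanks: list[Spectrum],
    cfg: PreprocessConfig | None = None,
) -> tuple[SpectralDataset, SpectralDataset]:
    """Run the full preprocessing chain on a raw single-channel dataset.

    Returns ``(fingerprints, autofluorescence)``: the Raman fingerprint
    dataset and the parallel dataset of fitted fluorescence baselines (same
    variable count, same row metadata).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate(d.n_variables)
    blocks = d.channel_blocks()
    if len(blocks) != 1:
        raise InvalidInputError("run_pipeline expects a single-channel dataset")
    if not blanks:
        raise MissingBlankError("no blank spectra supplied")

    work = despike_median(d) if cfg.despike == "multi_acquisition_median" else d.copy()

    axis = work.col_meta["wavenumber"].to_numpy()
    blank_stack = np.vstack(
        [
            resample_to_axis(b, axis).intensities
            for b in blanks
        ]
    )
    blank_mean = blank_stack.mean(axis=0)

    fingerprints = np.empty_like(work.matrix)
    fluorescence = np.empty_like(work.matrix)
    for i in range(work.n_spectra):
        y = work.matrix[i] - blank_mean
        y = _denoise(y, cfg.wavelet_levels)
        baseline = _poly_baseline(axis, y, cfg.poly_order)
        fluorescence[i] = baseline
        y = y - baseline
        y = np.maximum(y - _lower_hull_baseline(axis, y), 0.0)
        y[0] = 0.0
        y[-1] = 0.0
        if cfg.normalize == "vector":
            norm = np.linalg.norm(y)
            if norm == 0.0:
                raise DegenerateInputError(
                    f"row {i}: spectrum became all-zero during preprocessing"
                )
            y = y / norm
        fingerprints[i] = y
    logger.info(
        "preprocessed %d spectra (%d variables): wavelet levels=%d, "
        "poly order=%d, normalize=%s",
        work.n_spectra,
        work.n_variables,
        cfg.wavelet_levels,
        cfg.poly_order,
        cfg.normalize,
    )

    fp = work.copy()
    fp.matrix = fingerprints
    fluor = work.copy()
    fluor.matrix = fluorescence
    fluor.signal_kind = "autofluorescence"
    if cfg.standardize_for_pca:
        fp = standardize_columns(fp)
    return fp, fluor
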