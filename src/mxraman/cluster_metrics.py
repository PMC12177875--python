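"""Unsupervised cluster-structure evaluation.

Spectra (optionally reduced to a barcode) are standardized, projected onto
the first principal components, optionally transformed by LDA on those
scores, and then scored with two complementary cluster statistics:

* **Mahalanobis spread** — per class, the mean covariance-normalized
  distance of its points to their centroid in the PC1-PC2 plane; an
  anisotropy-aware intraclass-variance measure (smaller = tighter cluster);
* **Bhattacharyya distance** — for each class pair, the Gaussian overlap
  distance combining mean separation and covariance mismatch (larger =
  less overlap), averaged over all pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .barcode import Barcode, apply_barcode
from .errors import InvalidConfigError, InvalidInputError
from .preprocess import standardize_columns
from .spectral_io import SpectralDataset

logger = logging.getLogger(__name__)


@dataclass
class ProjectionResult:
    """Scores/loadings of a linear projection (PC or LD space)."""

    scores: np.ndarray  # n_spectra x n_components
    loadings: np.ndarray  # n_components x n_variables
    explained_variance_ratio: np.ndarray
    kind: str  # "PC" | "LD"
    mean: np.ndarray  # column means removed before projection


@dataclass
class SeparationReport:
    mahalanobis_spread: dict[str, float]
    bhattacharyya: pd.DataFrame  # symmetric class x class matrix
    average_bhattacharyya: float
    space: str  # "PCA" | "PCA-LDA"
    n_components: int

    def to_dict(self) -> dict:
        return {
            "space": self.space,
            "n_components": self.n_components,
            "mahalanobis_spread": {
                k: float(v) for k, v in self.mahalanobis_spread.items()
            },
            "bhattacharyya_pairwise": {
                a: {b: float(self.bhattacharyya.at[a, b]) for b in self.bhattacharyya}
                for a in self.bhattacharyya.index
            },
            "average_bhattacharyya": float(self.average_bhattacharyya),
        }


def pca_project(d: SpectralDataset, n_components: int = 3) -> ProjectionResult:
    """PCA scores via SVD of the column-centered matrix.

    Sign convention: each loading vector's largest-magnitude element is
    positive, making repeated runs bit-identical.
    """
    X = d.matrix
    if n_components > min(X.shape):
        raise InvalidConfigError(
            f"n_components={n_components} exceeds min(n_rows, n_cols)={min(X.shape)}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| loading element positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    total = float(np.sum(S**2))
    evr = S**2 / total if total > 0 else np.zeros_like(S)
    return ProjectionResult(
        scores=(U * S)[:, :n_components],
        loadings=Vt[:n_components],
        explained_variance_ratio=evr[:n_components],
        kind="PC",
        mean=mean,
    )


def _regularized_cov(x: np.ndarray) -> np.ndarray:
    """Sample covariance with a ridge when near-singular (logged)."""
    cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    dim = cov.shape[0]
    eigmin = np.linalg.eigvalsh(cov)[0]
    trace = float(np.trace(cov))
    if eigmin <= 1e-12 * max(trace, 1.0):
        eps = 1e-8 * trace / dim if trace > 0 else 1e-12
        eps = max(eps, 1e-12)
        logger.warning(
            "near-singular covariance regularized with ridge eps=%g", eps
        )
        cov = cov + eps * np.eye(dim)
    return cov


def mahalanobis_spread(
    scores: np.ndarray,
    labels: np.ndarray,
    covariance: str = "total",
) -> dict[str, float]:
    """Per-class mean Mahalanobis distance to the class centroid.

    Computed in the PC1-PC2 plane (the first two columns of ``scores``):
    for each class, the mean over its points of
    ``sqrt((x - mu_c)' S^-1 (x - mu_c))`` with ``mu_c`` the class centroid.

    With ``covariance="total"`` (default) ``S`` is the sample covariance of
    *all* scores — each point's distance to its cluster center is measured
    against the ellipsoid width of the full data cloud in that direction,
    so the statistic falls when intraclass variance shrinks relative to the
    retained between-class structure.  With ``covariance="per_class"`` each
    class is normalized by its own covariance; that variant is invariant
    under any affine transform of the class's points and measures cluster
    *shape* only (heavy tails / multimodality), not tightness.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[1] < 2:
        raise InvalidInputError("scores must have at least 2 components")
    if covariance not in ("total", "per_class"):
        raise InvalidInputError(f"unknown covariance mode {covariance!r}")
    pts2d = scores[:, :2]
    labels = np.asarray(labels)
    total_inv = (
        np.linalg.pinv(_regularized_cov(pts2d)) if covariance == "total" else None
    )
    out: dict[str, float] = {}
    for cls in sorted(set(map(str, labels))):
        pts = pts2d[labels.astype(str) == cls]
        if pts.shape[0] < 3:
            raise InvalidInputError(
                f"class {cls!r} has fewer than 3 points for Mahalanobis spread"
            )
        mu = pts.mean(axis=0)
        diff = pts - mu
        inv = (
            total_inv
            if total_inv is not None
            else np.linalg.pinv(_regularized_cov(pts))
        )
        d2 = np.einsum("ij,jk,ik->i", diff, inv, diff)
        out[cls] = float(np.mean(np.sqrt(np.maximum(d2, 0.0))))
    return out


def bhattacharyya_pair(scores_a: np.ndarray, scores_b: np.ndarray) -> float:
    """Gaussian Bhattacharyya distance between two point clouds.

    D_B = 1/8 (mu1-mu2)' S^-1 (mu1-mu2) + 1/2 ln[ det S / sqrt(det S1 det S2) ]
    with S = (S1+S2)/2 and sample means/covariances.  Symmetric, zero for
    identical clouds, invariant under common invertible affine transforms.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise InvalidInputError("groups live in different dimensions")
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise InvalidInputError("each group needs at least 3 points")
    mu_a, mu_b = a.mean(axis=0), b.mean(axis=0)
    cov_a = _regularized_cov(a)
    cov_b = _regularized_cov(b)
    cov_m = 0.5 * (cov_a + cov_b)
    diff = mu_a - mu_b
    term1 = 0.125 * diff @ np.linalg.solve(cov_m, diff)
    sign_m, logdet_m = np.linalg.slogdet(cov_m)
    sign_a, logdet_a = np.linalg.slogdet(cov_a)
    sign_b, logdet_b = np.linalg.slogdet(cov_b)
    if min(sign_m, sign_a, sign_b) <= 0:
        raise InvalidInputError("covariance not positive definite")
    term2 = 0.5 * (logdet_m - 0.5 * (logdet_a + logdet_b))
    return float(term1 + term2)


def separation_report(
    d: SpectralDataset,
    b: Barcode | None = None,
    use_lda: bool = False,
    n_components: int = 3,
) -> SeparationReport:
    """Cluster-separation metrics in PCA (or PCA-LDA) space.

    Pipeline: apply barcode (if given) -> standardize columns -> PCA with
    ``n_components`` -> optionally LDA on the PC scores (k-1 discriminants,
    first ``n_components`` retained) -> per-class Mahalanobis spreads on the
    first two retained components and pairwise Bhattacharyya distances on
    the full retained space.
    """
    ds = apply_barcode(d, b) if b is not None else d
    std = standardize_columns(ds)
    proj = pca_project(std, n_components=n_components)
    space = proj.scores
    kind = "PCA"
    labels = ds.labels
    classes = ds.classes
    if use_lda:
        # LDA needs at least k-1 input dimensions to yield its full k-1
        # discriminants (5 classes -> 4 LDs); retaining the first
        # n_components LDs is then a genuine projection, not an invertible
        # map of the PCA space (which would leave Bhattacharyya unchanged)
        n_in = min(max(len(classes) - 1, n_components), min(std.matrix.shape))
        lda_in = pca_project(std, n_components=n_in).scores
        lda = LinearDiscriminantAnalysis(n_components=min(n_in, len(classes) - 1))
        space = lda.fit_transform(lda_in, labels)[:, :n_components]
        kind = "PCA-LDA"

    spreads = mahalanobis_spread(space, labels)
    mat = pd.DataFrame(0.0, index=classes, columns=classes)
    pair_vals = []
    for i, ca in enumerate(classes):
        for cb in classes[i + 1 :]:
            val = bhattacharyya_pair(space[labels == ca], space[labels == cb])
            mat.at[ca, cb] = val
            mat.at[cb, ca] = val
            pair_vals.append(val)
    return SeparationReport(
        mahalanobis_spread=spreads,
        bhattacharyya=mat,
        average_bhattacharyya=float(np.mean(pair_vals)) if pair_vals else 0.0,
        space=kind,
        n_components=space.shape[1],
    )
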