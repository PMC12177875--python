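"""Supervised configuration comparison via cross-validated LDA.

The evaluation protocol deliberately mirrors a *configuration comparison*,
not predictive validation: each sample contributes spectra to both the
training and the test partition of every repeat (the first, middle and
final 3 acquisitions of each sample form test sets 1-3), so absolute
accuracies are optimistic.  What the protocol supports is a paired
comparison between acquisition configurations (single channel vs fused
multi-excitation, barcode sizes, ...) on identical sample structure.

The discriminant is a pooled-within-class-covariance Gaussian LDA.  When
the variable count reaches or exceeds the training count (p >= n), the
pooled covariance is inverted with its Moore-Penrose pseudo-inverse
("pseudo-linear" behavior), computed through a thin SVD of the
within-class-centered matrix so fitting stays cheap at p >> n.  On
full-rank problems this reduces exactly to classical LDA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    LabelError,
    SchemaError,
)
from .spectral_io import SpectralDataset

logger = logging.getLogger(__name__)

COMPARISON_NOTE = (
    "splits are correlated at sample level: results support configuration "
    "comparison, not predictive validation"
)


@dataclass
class SplitScheme:
    """Three train/test repeats from first/middle/final acquisitions."""

    repeats: list[tuple[np.ndarray, np.ndarray]]  # (train_idx, test_idx)


def make_splits(d: SpectralDataset) -> SplitScheme:
    """Per-sample positional splits: first, middle and final 3 acquisitions.

    Every sample must contribute the same number m > 3 of spectra.  For
    repeat r in {0,1,2} the test rows of each sample are the acquisitions
    at positions {0,1,2}, {m//2 - 1, m//2, m//2 + 1} and {m-3, m-2, m-1}
    (by acquisition order within the sample); the remainder trains.  With
    15 samples of 30 spectra this yields 405 train / 45 test per repeat.
    """
    meta = d.row_meta
    groups = meta.groupby("sample_id").indices
    counts = {s: len(ix) for s, ix in groups.items()}
    sizes = set(counts.values())
    if len(sizes) != 1:
        raise InvalidInputError(f"unequal per-sample spectrum counts: {counts}")
    m = sizes.pop()
    if m <= 3:
        raise InvalidConfigError(
            f"need more than 3 spectra per sample (got {m}) so every repeat "
            "has a non-empty training set"
        )
    positions = [
        np.array([0, 1, 2]),
        np.array([m // 2 - 1, m // 2, m // 2 + 1]),
        np.array([m - 3, m - 2, m - 1]),
    ]
    repeats = []
    for pos in positions:
        test: list[int] = []
        for sample, idx in groups.items():
            idx = np.asarray(idx)
            order = idx[np.argsort(meta["acquisition_index"].to_numpy()[idx], kind="stable")]
            test.extend(order[pos])
        test_idx = np.sort(np.asarray(test, dtype=int))
        mask = np.ones(d.n_spectra, dtype=bool)
        mask[test_idx] = False
        repeats.append((np.nonzero(mask)[0], test_idx))
    return SplitScheme(repeats=repeats)


class LDAModel:
    """Pooled-covariance Gaussian LDA with pseudo-inverse fallback."""

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self.col_meta: pd.DataFrame | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LDAModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.array(sorted(set(map(str, y))))
        n, p = X.shape
        k = len(self.classes_)
        if k < 2:
            raise LabelError("LDA needs at least 2 classes")
        means = np.vstack(
            [X[y.astype(str) == c].mean(axis=0) for c in self.classes_]
        )
        counts = np.array([np.sum(y.astype(str) == c) for c in self.classes_])
        self.priors_ = counts / n
        Xw = X.copy()
        for i, c in enumerate(self.classes_):
            Xw[y.astype(str) == c] -= means[i]
        # pooled covariance = V diag(s^2/(n-k)) V' from the thin SVD of Xw;
        # its pseudo-inverse whitens through W = V diag(sqrt(n-k)/s)
        _, s, Vt = np.linalg.svd(Xw, full_matrices=False)
        rcond = max(n, p) * np.finfo(float).eps
        keep = s > rcond * (s[0] if s.size else 0.0)
        if not np.any(keep):
            # all classes identical pointwise: fall back to prior-only scores
            self._W = np.zeros((p, 1))
        else:
            self._W = (Vt[keep].T / s[keep]) * np.sqrt(max(n - k, 1))
        self._means_w = means @ self._W
        self._log_priors = np.log(self.priors_)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float) @ self._W
        # linear discriminant score z.m - ||m||^2/2 + log prior
        return (
            Z @ self._means_w.T
            - 0.5 * np.sum(self._means_w**2, axis=1)
            + self._log_priors
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes_[np.argmax(scores, axis=1)]


@dataclass
class CVResult:
    per_class_accuracy: dict[str, float]  # percent
    overall_accuracy: float  # percent
    folds: int
    seed: int


def train_lda(
    train: SpectralDataset, folds: int = 5, seed: int = 0
) -> tuple[LDAModel, CVResult]:
    """Fit LDA with stratified k-fold cross-validation on the training set.

    Returns the model refit on all training rows plus per-class and overall
    CV accuracy (percent).  Stratification guarantees every class appears
    in every fold; classes with fewer members than folds are rejected.
    """
    y = train.labels.astype(str)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < folds):
        raise InvalidConfigError(
            f"every class needs at least {folds} training spectra"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    for tr, va in skf.split(train.matrix, y):
        model = LDAModel().fit(train.matrix[tr], y[tr])
        pred = model.predict(train.matrix[va])
        for yi, pi in zip(y[va], pred):
            total[yi] += 1
            correct[yi] += int(yi == pi)
    per_class = {c: 100.0 * correct[c] / total[c] for c in classes}
    overall = 100.0 * sum(correct.values()) / sum(total.values())
    model = LDAModel().fit(train.matrix, y)
    model.col_meta = train.col_meta.copy()
    return model, CVResult(
        per_class_accuracy=per_class,
        overall_accuracy=overall,
        folds=folds,
        seed=seed,
    )


def evaluate(
    model: LDAModel, test: SpectralDataset
) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-class test accuracy (percent) and the confusion matrix.

    Confusion rows are true classes, columns predicted classes; each row
    sums to that class's test count.
    """
    if model.col_meta is not None:
        if len(model.col_meta) != test.n_variables or not np.allclose(
            model.col_meta["wavenumber"].to_numpy(),
            test.col_meta["wavenumber"].to_numpy(),
            rtol=0,
            atol=1e-9,
        ) or list(model.col_meta["channel"]) != list(test.col_meta["channel"]):
            raise SchemaError("test dataset column map differs from the model's")
    y = test.labels.astype(str)
    unknown = set(y) - set(model.classes_)
    if unknown:
        raise LabelError(f"test classes unknown to the model: {sorted(unknown)}")
    pred = model.predict(test.matrix)
    classes = list(model.classes_)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for yi, pi in zip(y, pred):
        conf.at[yi, pi] += 1
    present = sorted(set(y))
    acc = {
        c: 100.0 * conf.at[c, c] / conf.loc[c].sum() for c in present
    }
    return acc, conf


@dataclass
class EvaluationReport:
    """Per-configuration accuracies across repeats plus pairwise comparisons."""

    per_config: dict[str, dict] = field(default_factory=dict)
    comparisons: dict = field(default_factory=dict)
    note: str = COMPARISON_NOTE

    def accuracy_values(self, name: str) -> np.ndarray:
        """The (class x repeat) test accuracy values for one configuration."""
        return np.asarray(self.per_config[name]["values"], dtype=float)

    def to_dict(self) -> dict:
        out = {"note": self.note, "configurations": {}, "comparisons": {}}
        for name, rec in self.per_config.items():
            out["configurations"][name] = {
                "mean_accuracy": rec["mean"],
                "sd_accuracy": rec["sd"],
                "values": list(map(float, rec["values"])),
                "train_cv_overall": rec["train_cv_overall"],
                "per_repeat": rec["per_repeat"],
            }
        for key, rec in self.comparisons.get("pairwise", {}).items():
            out["comparisons"][" vs ".join(key)] = rec
        out["omnibus"] = {
            "H": self.comparisons.get("omnibus_H"),
            "p": self.comparisons.get("omnibus_p"),
        }
        return out


def run_protocol(
    configs: dict[str, SpectralDataset],
    seed: int = 0,
    folds: int = 5,
) -> EvaluationReport:
    """Run the full split/train/evaluate protocol on named configurations.

    For each configuration: positional splits -> per repeat, stratified
    5-fold CV LDA training and test evaluation -> k classes x 3 repeats
    class-level test accuracies, summarized as mean +- sd.  Configurations
    are then compared with Kruskal-Wallis and Bonferroni-corrected
    Dunn-style pairwise tests.
    """
    if not configs:
        raise InvalidInputError("no configurations supplied")
    names = list(configs)
    ref = configs[names[0]].row_meta
    for name in names[1:]:
        meta = configs[name].row_meta
        if not ref[["class_label", "sample_id"]].sort_values(
            ["class_label", "sample_id"]
        ).reset_index(drop=True).equals(
            meta[["class_label", "sample_id"]]
            .sort_values(["class_label", "sample_id"])
            .reset_index(drop=True)
        ):
            raise InvalidInputError(
                f"configuration {name!r} has different row metadata"
            )

    report = EvaluationReport()
    for ci, name in enumerate(names):
        d = configs[name]
        splits = make_splits(d)
        values: list[float] = []
        per_repeat = []
        cv_overalls = []
        for r, (train_idx, test_idx) in enumerate(splits.repeats):
            fold_seed = (seed * 9973 + ci * 97 + r) % (2**31)
            train = _subset_rows(d, train_idx)
            test = _subset_rows(d, test_idx)
            model, cv = train_lda(train, folds=folds, seed=fold_seed)
            acc, conf = evaluate(model, test)
            for cls in sorted(acc):
                values.append(acc[cls])
            per_repeat.append(
                {
                    "repeat": r,
                    "test_per_class": {k: float(v) for k, v in acc.items()},
                    "train_cv_per_class": {
                        k: float(v) for k, v in cv.per_class_accuracy.items()
                    },
                    "confusion": conf.to_dict(),
                }
            )
            cv_overalls.append(cv.overall_accuracy)
        arr = np.asarray(values)
        report.per_config[name] = {
            "values": values,
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "train_cv_overall": float(np.mean(cv_overalls)),
            "per_repeat": per_repeat,
        }
        logger.info(
            "config %s: test accuracy %.1f%% +- %.1f%%",
            name,
            report.per_config[name]["mean"],
            report.per_config[name]["sd"],
        )
    if len(names) >= 2:
        report.comparisons = compare_configs(
            {n: report.per_config[n]["values"] for n in names}
        )
    return report


def _subset_rows(d: SpectralDataset, idx: np.ndarray) -> SpectralDataset:
    return d.subset_rows(idx)


def compare_configs(accuracy_sets: dict[str, list[float]]) -> dict:
    """Kruskal-Wallis omnibus plus Dunn-style pairwise rank tests.

    Pairwise two-sided p-values are Bonferroni-multiplied by the number of
    pairs (capped at 1).  Identical sets give H = 0, p = 1.
    """
    names = list(accuracy_sets)
    if len(names) < 2:
        raise InvalidInputError("need at least 2 configurations to compare")
    sets = [np.asarray(accuracy_sets[n], dtype=float) for n in names]
    sizes = {len(s) for s in sets}
    if len(sizes) != 1:
        raise InvalidInputError("accuracy sets have unequal sizes")

    pooled = np.concatenate(sets)
    if np.all(pooled == pooled[0]):
        omnibus_h, omnibus_p = 0.0, 1.0
        ranks = stats.rankdata(pooled)
        var_term = 0.0
    else:
        omnibus_h, omnibus_p = stats.kruskal(*sets)
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_sum = float(np.sum(tie_counts**3 - tie_counts))
        var_term = n_total * (n_total + 1) / 12.0 - tie_sum / (
            12.0 * (n_total - 1)
        )

    # mean rank per configuration
    offsets = np.cumsum([0] + [len(s) for s in sets])
    mean_ranks = [
        float(np.mean(ranks[offsets[i] : offsets[i + 1]]))
        for i in range(len(sets))
    ]
    n_pairs = len(names) * (len(names) - 1) // 2
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if var_term <= 0:
                z, p_raw = 0.0, 1.0
            else:
                se = np.sqrt(var_term * (1.0 / len(sets[i]) + 1.0 / len(sets[j])))
                z = (mean_ranks[i] - mean_ranks[j]) / se
                p_raw = float(2.0 * stats.norm.sf(abs(z)))
            pairwise[(names[i], names[j])] = {
                "z": float(z),
                "p_raw": p_raw,
                "p_bonferroni": float(min(1.0, p_raw * n_pairs)),
            }
    return {
        "omnibus_H": float(omnibus_h),
        "omnibus_p": float(omnibus_p),
        "pairwise": pairwise,
    }
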