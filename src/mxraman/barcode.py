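"""Spectral barcode engineering.

A *spectral barcode* is a minimal ordered subset of dataset variables, each
flagged as increased ("black") or decreased ("gray") in the disease class,
engineered to retain class-descriptive information while discarding
redundant variance.  Three families are provided:

* **disease barcodes** — per-wavenumber two-sided Mann-Whitney U tests of
  one disease class against the control class; the three top-ranked
  variables in *independent* (disjoint, unbroken, within-channel) runs of
  significant variables seed three spectral regions, and every variable of
  each region enters the barcode;
* **universal barcodes** — all k(k-1)/2 pairwise class tests; the per-test
  top-10 variables are reduced with a greedy minimum-redundancy
  maximum-relevance (mRMR) step and combined into barcodes of exact size
  (100, 30, 10, half of the variables, or all of them);
* **negative control** — the k variables *least* associated with class by
  one-way ANOVA.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import mutual_info_score

from .errors import (
    InvalidConfigError,
    InvalidInputError,
    LabelError,
    MappingError,
)
from .spectral_io import SpectralDataset

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 20  # largest group size for the exact U null distribution
_EXACT_MAX_COMBS = 200_000  # enumeration budget for the tie-aware exact null


@dataclass
class FeatureRanking:
    """Per-variable Mann-Whitney U results for one class pair.

    ``rank`` is a permutation of 1..n_variables: 1 = most significant, ties
    broken by larger absolute median difference, then lower column index.
    ``direction`` is the sign of (median of class_b - median of class_a).
    """

    class_a: str
    class_b: str
    u: np.ndarray
    p: np.ndarray
    median_diff: np.ndarray
    direction: np.ndarray
    rank: np.ndarray

    @property
    def order(self) -> np.ndarray:
        """Column indices from most to least significant."""
        return np.argsort(self.rank)

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]


@dataclass
class SpectralRegion:
    """A maximal unbroken run of significant variables within one channel."""

    channel: str
    start: int
    end: int  # inclusive
    seed: int

    @property
    def columns(self) -> np.ndarray:
        return np.arange(self.start, self.end + 1)


@dataclass
class BarcodeVariable:
    column: int
    channel: str
    wavenumber: float
    direction: int  # +1 increase (black), -1 decrease (gray), 0 undirected
    provenance: str
    mrmr_rank: int | None = None


@dataclass
class Barcode:
    """Ordered subset of dataset variables with direction flags."""

    name: str
    variables: list[BarcodeVariable] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = [v.column for v in self.variables]
        if len(cols) != len(set(cols)):
            raise InvalidInputError(f"barcode {self.name!r} has duplicate variables")

    @property
    def size(self) -> int:
        return len(self.variables)

    @property
    def columns(self) -> np.ndarray:
        return np.asarray([v.column for v in self.variables], dtype=int)

    def channels(self) -> set[str]:
        return {v.channel for v in self.variables}

    def to_records(self) -> list[dict]:
        return [
            {
                "column": int(v.column),
                "channel": v.channel,
                "wavenumber": float(v.wavenumber),
                "direction": int(v.direction),
                "provenance": v.provenance,
                "mrmr_rank": v.mrmr_rank,
            }
            for v in self.variables
        ]

    @classmethod
    def from_records(cls, name: str, records: list[dict]) -> "Barcode":
        return cls(
            name,
            [
                BarcodeVariable(
                    column=int(r["column"]),
                    channel=str(r["channel"]),
                    wavenumber=float(r["wavenumber"]),
                    direction=int(r["direction"]),
                    provenance=str(r.get("provenance", "")),
                    mrmr_rank=r.get("mrmr_rank"),
                )
                for r in records
            ],
        )


# ---------------------------------------------------------------------------
# per-wavenumber ranking
# ---------------------------------------------------------------------------

def _class_rows(d: SpectralDataset, label: str) -> np.ndarray:
    mask = d.labels == label
    if not mask.any():
        raise LabelError(f"class {label!r} absent from dataset")
    return d.matrix[mask]


import functools as _functools
from math import comb as _comb


def _n_combinations(na: int, nb: int) -> int:
    return _comb(na + nb, na)


@_functools.lru_cache(maxsize=8)
def _combination_indices(na: int, nb: int) -> np.ndarray:
    """All C(na+nb, na) index subsets of size na, as a 2-D int array."""
    return np.array(
        list(itertools.combinations(range(na + nb), na)), dtype=np.intp
    )


def _exact_tied_utest(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact permutation Mann-Whitney U with midranks (tie-aware).

    Enumerates every assignment of the pooled (mid)ranks to the first
    group; the two-sided p-value doubles the smaller tail of the observed
    U under this permutation null, capped at 1.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    na = x.size
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2.0)
    combs = _combination_indices(na, y.size)
    u_all = ranks[combs].sum(axis=1) - na * (na + 1) / 2.0
    tol = 1e-9
    p_hi = np.mean(u_all >= u_obs - tol)
    p_lo = np.mean(u_all <= u_obs + tol)
    return u_obs, float(min(1.0, 2.0 * min(p_hi, p_lo)))


def rank_utest(
    d: SpectralDataset, class_a: str, class_b: str
) -> FeatureRanking:
    """Two-sided Mann-Whitney U per variable between two classes.

    For small groups (both at most 20 members) the exact null distribution
    is used: scipy's exact method on untied columns, and a tie-aware exact
    permutation enumeration on tied columns whenever the number of
    assignments is at most 200 000.  Everything else falls back to the
    normal approximation with tie correction.  Ranking follows p-value
    ascending, then larger absolute median difference, then lower column
    index.
    """
    a = _class_rows(d, class_a)
    b = _class_rows(d, class_b)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidInputError("each class needs at least 2 spectra")

    if a.shape[0] <= _EXACT_MAX_N and b.shape[0] <= _EXACT_MAX_N:
        u = np.empty(d.n_variables)
        p = np.empty(d.n_variables)
        for j in range(d.n_variables):
            col_a, col_b = a[:, j], b[:, j]
            pooled = np.concatenate([col_a, col_b])
            if np.unique(pooled).size == pooled.size:
                res = stats.mannwhitneyu(
                    col_a, col_b, alternative="two-sided", method="exact"
                )
                u[j], p[j] = res.statistic, res.pvalue
            elif _n_combinations(col_a.size, col_b.size) <= _EXACT_MAX_COMBS:
                u[j], p[j] = _exact_tied_utest(col_a, col_b)
            else:
                res = stats.mannwhitneyu(
                    col_a, col_b, alternative="two-sided", method="asymptotic"
                )
                u[j], p[j] = res.statistic, res.pvalue
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", axis=0
        )
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)

    median_diff = np.median(b, axis=0) - np.median(a, axis=0)
    direction = np.sign(median_diff).astype(int)
    order = np.lexsort((np.arange(d.n_variables), -np.abs(median_diff), p))
    rank = np.empty(d.n_variables, dtype=int)
    rank[order] = np.arange(1, d.n_variables + 1)
    return FeatureRanking(
        class_a=class_a,
        class_b=class_b,
        u=u,
        p=p,
        median_diff=median_diff,
        direction=direction,
        rank=rank,
    )


# ---------------------------------------------------------------------------
# regions and disease barcodes
# ---------------------------------------------------------------------------

def select_regions(
    r: FeatureRanking,
    d: SpectralDataset,
    n_regions: int = 3,
    alpha: float = 0.05,
) -> list[SpectralRegion]:
    """Pick the top-ranked variables in independent significant regions.

    A region is a maximal unbroken run of variables with p < ``alpha`` that
    never crosses a channel-block boundary.  Regions are seeded, in rank
    order, by the best-ranked significant variables not already inside a
    chosen region, so the returned regions are pairwise disjoint.  If fewer
    than ``n_regions`` disjoint significant runs exist, all of them are
    returned with a warning.
    """
    if n_regions < 1:
        raise InvalidConfigError("n_regions must be >= 1")
    sig = r.p < alpha
    run_id = np.full(d.n_variables, -1, dtype=int)
    runs: list[SpectralRegion] = []
    for tag, sl in d.channel_blocks():
        start = None
        for j in range(sl.start, sl.stop + 1):
            inside = j < sl.stop and sig[j]
            if inside and start is None:
                start = j
            elif not inside and start is not None:
                runs.append(SpectralRegion(tag, start, j - 1, seed=start))
                run_id[start:j] = len(runs) - 1
                start = None

    chosen: list[SpectralRegion] = []
    taken: set[int] = set()
    for col in r.order:
        if not sig[col]:
            break  # ranking is p-ascending first, so no significant columns remain
        rid = run_id[col]
        if rid in taken:
            continue
        region = runs[rid]
        chosen.append(
            SpectralRegion(region.channel, region.start, region.end, seed=int(col))
        )
        taken.add(rid)
        if len(chosen) == n_regions:
            break
    if len(chosen) < n_regions:
        logger.warning(
            "select_regions: only %d of %d requested significant regions found",
            len(chosen),
            n_regions,
        )
    return chosen


def disease_barcode(
    d: SpectralDataset,
    control: str,
    disease: str,
    n_regions: int = 3,
    alpha: float = 0.05,
) -> Barcode:
    """Disease-specific barcode: control-vs-disease U test, 3 top regions.

    Every variable of each selected region enters the barcode; direction
    flags come from the sign of the disease-minus-control median difference
    (+1 = increase/black, -1 = decrease/gray).
    """
    ranking = rank_utest(d, control, disease)
    regions = select_regions(ranking, d, n_regions=n_regions, alpha=alpha)
    if not regions:
        logger.warning(
            "disease_barcode: no significant regions for %s vs %s; empty barcode",
            disease,
            control,
        )
    wn = d.col_meta["wavenumber"].to_numpy()
    ch = d.col_meta["channel"].to_numpy()
    variables = []
    for i, region in enumerate(regions):
        for col in region.columns:
            variables.append(
                BarcodeVariable(
                    column=int(col),
                    channel=str(ch[col]),
                    wavenumber=float(wn[col]),
                    direction=int(ranking.direction[col]),
                    provenance=(
                        f"utest:{control}|{disease};region:{i};seed:{region.seed}"
                    ),
                )
            )
    return Barcode(name=f"{disease}_vs_{control}", variables=variables)


# ---------------------------------------------------------------------------
# mRMR and universal barcodes
# ---------------------------------------------------------------------------

def _discretize_deciles(col: np.ndarray) -> np.ndarray:
    edges = np.unique(np.quantile(col, np.linspace(0.1, 0.9, 9)))
    return np.digitize(col, edges)


def mrmr_select(
    d: SpectralDataset, candidates, k: int
) -> list[int]:
    """Greedy mRMR (difference criterion) over candidate columns.

    Relevance is the mutual information between the decile-discretized
    variable and the class label; redundancy is the mean mutual information
    with already-selected variables.  The first pick maximizes relevance;
    subsequent picks maximize relevance minus mean redundancy.  Ties break
    deterministically to the lower column index.
    """
    candidates = [int(c) for c in candidates]
    if k > len(candidates):
        raise InvalidConfigError(
            f"k={k} exceeds the {len(candidates)} candidate variables"
        )
    labels = d.labels
    disc = {c: _discretize_deciles(d.matrix[:, c]) for c in candidates}
    relevance = {c: mutual_info_score(labels, disc[c]) for c in candidates}
    pair_mi: dict[tuple[int, int], float] = {}

    def mi(c1: int, c2: int) -> float:
        key = (min(c1, c2), max(c1, c2))
        if key not in pair_mi:
            pair_mi[key] = mutual_info_score(disc[c1], disc[c2])
        return pair_mi[key]

    selected: list[int] = []
    remaining = list(candidates)
    while len(selected) < k:
        best_col, best_score = None, -np.inf
        for c in remaining:
            if selected:
                redundancy = float(np.mean([mi(c, s) for s in selected]))
                score = relevance[c] - redundancy
            else:
                score = relevance[c]
            if score > best_score or (score == best_score and c < best_col):
                best_col, best_score = c, score
        selected.append(best_col)
        remaining.remove(best_col)
    return selected


def _round_robin_fill(
    per_test: list[list[int]], initial: list[int], target: int
) -> list[int]:
    """Fill to exact size from per-test candidate lists, round-robin."""
    selected = list(initial)
    used = set(selected)
    pointers = [0] * len(per_test)
    while len(selected) < target:
        advanced = False
        for t, cand in enumerate(per_test):
            while pointers[t] < len(cand) and cand[pointers[t]] in used:
                pointers[t] += 1
            if pointers[t] < len(cand):
                col = cand[pointers[t]]
                selected.append(col)
                used.add(col)
                pointers[t] += 1
                advanced = True
                if len(selected) == target:
                    break
        if not advanced:
            break  # all candidate lists exhausted
    return selected


def universal_barcode(
    d: SpectralDataset,
    size,
    top_per_test: int = 10,
    mrmr_per_test: int = 3,
) -> Barcode:
    """Universal multi-class barcode from all pairwise class tests.

    With k classes, k(k-1)/2 pairwise U tests are performed.  Sizes:

    * ``"full"`` — every variable, ordered by best (minimum) pairwise p;
    * ``"half"`` — the top half of that global ordering;
    * ``100`` — union of per-test top-10 variables, backfilled from the
      tests' next-ranked variables to the exact size;
    * ``30`` — per test, the top-10 variables are mRMR-reduced to 3; union
      backfilled (from each test's further mRMR ordering) to exactly 30;
    * ``10`` — the single top mRMR variable of each test, backfilled to 10.

    Each variable's direction flag comes from the test that contributed it.
    """
    classes = d.classes
    if len(classes) < 2:
        raise LabelError("universal barcode needs at least 2 classes")
    pairs = list(itertools.combinations(classes, 2))
    rankings = [rank_utest(d, a, b) for a, b in pairs]

    wn = d.col_meta["wavenumber"].to_numpy()
    ch = d.col_meta["channel"].to_numpy()

    def build(cols: list[int], contributors: dict[int, tuple[int, int | None]],
              name: str) -> Barcode:
        variables = []
        for col in cols:
            t, mrank = contributors.get(col, (None, None))
            if t is None:
                best = int(np.argmin([r.p[col] for r in rankings]))
                t, mrank = best, None
            r = rankings[t]
            variables.append(
                BarcodeVariable(
                    column=int(col),
                    channel=str(ch[col]),
                    wavenumber=float(wn[col]),
                    direction=int(r.direction[col]),
                    provenance=f"utest:{r.class_a}|{r.class_b};rank:{r.rank[col]}",
                    mrmr_rank=mrank,
                )
            )
        return Barcode(name=name, variables=variables)

    if size in ("full", "half"):
        p_best = np.min(np.vstack([r.p for r in rankings]), axis=0)
        best_test = np.argmin(np.vstack([r.p for r in rankings]), axis=0)
        order = np.lexsort((np.arange(d.n_variables), p_best))
        cols = list(order if size == "full" else order[: d.n_variables // 2])
        contributors = {int(c): (int(best_test[c]), None) for c in cols}
        return build(cols, contributors, f"universal_{size}")

    size = int(size)
    per_test_top = [list(map(int, r.top(top_per_test))) for r in rankings]

    if size == top_per_test * len(pairs):  # e.g. 100 for 5 classes
        initial: list[int] = []
        contributors: dict[int, tuple[int, int | None]] = {}
        used: set[int] = set()
        for t, cand in enumerate(per_test_top):
            for col in cand:
                if col not in used:
                    initial.append(col)
                    used.add(col)
                    contributors[col] = (t, None)
        full_orders = [list(map(int, r.order)) for r in rankings]
        cols = _round_robin_fill(full_orders, initial, size)
        for col in cols:
            if col not in contributors:
                contributors[col] = (
                    int(np.argmin([r.p[col] for r in rankings])),
                    None,
                )
        return build(cols, contributors, f"universal_{size}")

    # mRMR-based sizes: per-test mRMR ordering of its top candidates
    mrmr_orders = [
        mrmr_select(d, cand, k=len(cand)) for cand in per_test_top
    ]
    if size == mrmr_per_test * len(pairs):  # e.g. 30
        take = mrmr_per_test
    elif size == len(pairs):  # e.g. 10
        take = 1
    else:
        raise InvalidConfigError(
            f"unsupported universal barcode size {size} for {len(pairs)} "
            f"pairwise tests (supported: 'full', 'half', "
            f"{top_per_test * len(pairs)}, {mrmr_per_test * len(pairs)}, "
            f"{len(pairs)})"
        )
    initial = []
    contributors = {}
    used = set()
    for t, cand in enumerate(mrmr_orders):
        for mrank, col in enumerate(cand[:take], start=1):
            if col not in used:
                initial.append(col)
                used.add(col)
                contributors[col] = (t, mrank)
    cols = _round_robin_fill(mrmr_orders, initial, size)
    for col in cols:
        if col not in contributors:
            for t, cand in enumerate(mrmr_orders):
                if col in cand:
                    contributors[col] = (t, cand.index(col) + 1)
                    break
    return build(cols, contributors, f"universal_{size}")


# ---------------------------------------------------------------------------
# negative control and application
# ---------------------------------------------------------------------------

def lowest_ranked_anova(d: SpectralDataset, k: int = 10) -> Barcode:
    """The k variables least associated with class by one-way ANOVA.

    Constant columns have an undefined F statistic; they are assigned p = 1
    (logged) and are eligible for selection.  Used as a negative control:
    these variables should carry near-zero class information.
    """
    classes = d.classes
    if len(classes) < 2:
        raise LabelError("ANOVA ranking needs at least 2 classes")
    groups = [d.matrix[d.labels == c] for c in classes]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        _, p = stats.f_oneway(*groups, axis=0)
    p = np.asarray(p, dtype=float)
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning(
            "lowest_ranked_anova: %d constant column(s) assigned p = 1",
            int(bad.sum()),
        )
        p[bad] = 1.0
    order = np.lexsort((np.arange(d.n_variables), -p))
    cols = order[: min(k, d.n_variables)]
    wn = d.col_meta["wavenumber"].to_numpy()
    ch = d.col_meta["channel"].to_numpy()
    variables = [
        BarcodeVariable(
            column=int(c),
            channel=str(ch[c]),
            wavenumber=float(wn[c]),
            direction=0,
            provenance=f"anova:lowest;p:{p[c]:.6g}",
        )
        for c in cols
    ]
    return Barcode(name=f"anova_lowest_{len(cols)}", variables=variables)


def apply_barcode(d: SpectralDataset, b: Barcode) -> SpectralDataset:
    """Column-subset a dataset to the barcode's variables, in barcode order."""
    if b.size == 0:
        raise MappingError(f"barcode {b.name!r} is empty")
    wn = d.col_meta["wavenumber"].to_numpy()
    ch = d.col_meta["channel"].to_numpy()
    for v in b.variables:
        if not (0 <= v.column < d.n_variables):
            raise MappingError(f"barcode column {v.column} outside dataset")
        if str(ch[v.column]) != v.channel or abs(wn[v.column] - v.wavenumber) > 1e-9:
            raise MappingError(
                f"barcode variable ({v.channel}, {v.wavenumber:g}) does not "
                f"match dataset column {v.column}"
            )
    return d.select_columns(b.columns)
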