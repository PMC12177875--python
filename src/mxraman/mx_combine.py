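"""Fusion of fingerprints from multiple acquisition configurations.

Multi-excitation (MX) spectra are built by end-on-end concatenation of
per-channel fingerprints: each output row is the concatenation of one
spectrum per channel from the same sample (paired by acquisition index by
default).  The same mechanism fuses Raman with autofluorescence signals,
and :func:`depolarization_spectrum` forms per-variable depolarization
ratios rho = I_perp / I_par from paired polarized acquisitions (rho < 0.75
indicates a totally symmetric vibration).

No joint renormalization is applied after concatenation: each block keeps
its own (typically unit) norm, and per-block values are preserved
bit-exactly.  The total variable count is always the exact sum of the block
sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DegenerateInputError,
    InvalidInputError,
    PairingError,
)
from .spectral_io import SpectralDataset

logger = logging.getLogger(__name__)

PAIRINGS = ("by_acquisition_index", "by_rank_within_sample")


@dataclass
class MXSpectrumSet:
    """A concatenated multi-channel dataset plus its fusion provenance."""

    dataset: SpectralDataset
    provenance: list[str] = field(default_factory=list)
    pairing: str = "by_acquisition_index"

    @property
    def blocks(self) -> list[tuple[str, int]]:
        """(channel tag, variable count) per block, in concatenation order."""
        return [
            (tag, sl.stop - sl.start) for tag, sl in self.dataset.channel_blocks()
        ]


def _sorted_row_order(d: SpectralDataset) -> np.ndarray:
    meta = d.row_meta
    return np.lexsort(
        (
            meta["acquisition_index"].to_numpy(),
            meta["sample_id"].to_numpy(),
            meta["class_label"].to_numpy(),
        )
    )


def _check_pairable(
    datasets: list[SpectralDataset], pairing: str
) -> list[np.ndarray]:
    """Validate sample structure and return the aligned row order per dataset."""
    if pairing not in PAIRINGS:
        raise InvalidInputError(f"unknown pairing mode {pairing!r}")
    ref = datasets[0].row_meta
    ref_counts = ref.groupby("sample_id").size().sort_index()
    ref_classes = (
        ref.groupby("sample_id")["class_label"].first().sort_index()
    )
    orders = []
    for d in datasets:
        meta = d.row_meta
        counts = meta.groupby("sample_id").size().sort_index()
        if not counts.index.equals(ref_counts.index):
            raise PairingError("datasets do not share the same sample ids")
        if not counts.equals(ref_counts):
            raise PairingError("per-sample spectrum counts differ between datasets")
        classes = meta.groupby("sample_id")["class_label"].first().sort_index()
        if not classes.equals(ref_classes):
            raise PairingError("sample class labels differ between datasets")
        order = _sorted_row_order(d)
        if pairing == "by_acquisition_index":
            ref_order = _sorted_row_order(datasets[0])
            a = datasets[0].row_meta.iloc[ref_order]
            b = meta.iloc[order]
            if not np.array_equal(
                a["acquisition_index"].to_numpy(), b["acquisition_index"].to_numpy()
            ) or not np.array_equal(
                a["sample_id"].to_numpy(), b["sample_id"].to_numpy()
            ):
                raise PairingError(
                    "acquisition indices do not match across datasets; "
                    "use pairing='by_rank_within_sample'"
                )
        orders.append(order)
    return orders


def _dedupe_channels(
    col_parts: list[pd.DataFrame], block_lists: list[list[tuple[str, int]]]
) -> pd.DataFrame:
    """Suffix repeated channel tags so column lookup stays injective.

    Block identity comes from the source datasets, so self-concatenation
    (identical adjacent tags) still yields distinct tags per block.
    """
    seen: dict[str, int] = {}
    tags: list[str] = []
    for part, blocks in zip(col_parts, block_lists):
        for tag, count in blocks:
            seen[tag] = seen.get(tag, 0) + 1
            final = tag if seen[tag] == 1 else f"{tag}#{seen[tag]}"
            tags.extend([final] * count)
    out = pd.concat(col_parts, ignore_index=True)
    out["channel"] = tags
    return out


def concatenate(
    datasets: list[SpectralDataset],
    pairing: str = "by_acquisition_index",
) -> MXSpectrumSet:
    """End-on-end concatenation of per-channel fingerprint datasets.

    All datasets must cover the same samples with the same per-sample
    spectrum counts.  Row *i* of the output is the concatenation of the
    paired rows; per-block values are copied bit-exactly and the column map
    records block boundaries.  Concatenating a single dataset returns it
    unchanged (modulo a copy).
    """
    if not datasets:
        raise InvalidInputError("no datasets to concatenate")
    orders = _check_pairable(datasets, pairing)
    parts = [d.matrix[order] for d, order in zip(datasets, orders)]
    col_parts = [d.col_meta.copy() for d in datasets]
    col_meta = _dedupe_channels(col_parts, [_blocks_of(d) for d in datasets])
    row_meta = datasets[0].row_meta.iloc[orders[0]].reset_index(drop=True)
    merged = SpectralDataset(
        np.hstack(parts), row_meta, col_meta, signal_kind=datasets[0].signal_kind
    )
    provenance = [tag for d in datasets for tag, _ in _blocks_of(d)]
    return MXSpectrumSet(merged, provenance=provenance, pairing=pairing)


def _blocks_of(d: SpectralDataset) -> list[tuple[str, int]]:
    return [(tag, sl.stop - sl.start) for tag, sl in d.channel_blocks()]


def depolarization_spectrum(
    par: SpectralDataset,
    perp: SpectralDataset,
    floor: float | None = None,
    pairing: str = "by_acquisition_index",
) -> SpectralDataset:
    """Per-variable depolarization ratio rho = I_perp / I_par.

    The parallel intensity is floored at ``floor`` (default: 1e-6 of the
    parallel dataset's maximum) to avoid division blow-ups; floored entries
    are counted in the log.
    """
    wn_par = par.col_meta["wavenumber"].to_numpy()
    wn_perp = perp.col_meta["wavenumber"].to_numpy()
    if wn_par.size != wn_perp.size or not np.allclose(
        wn_par, wn_perp, rtol=0, atol=1e-9
    ):
        raise AlignmentError("parallel and perpendicular axes do not match")
    orders = _check_pairable([par, perp], pairing)
    p = par.matrix[orders[0]]
    s = perp.matrix[orders[1]]
    if floor is None:
        peak = float(np.max(p)) if p.size else 0.0
        floor = 1e-6 * peak if peak > 0 else 1e-12
    denom = np.maximum(p, floor)
    n_floored = int(np.sum(p < floor))
    if n_floored:
        logger.warning(
            "depolarization_spectrum: %d parallel intensities floored at %g",
            n_floored,
            floor,
        )
    rho = s / denom
    col_meta = par.col_meta.copy()
    col_meta["channel"] = [
        f"rho-{t}" if not str(t).startswith("rho-") else str(t)
        for t in col_meta["channel"]
    ]
    row_meta = par.row_meta.iloc[orders[0]].reset_index(drop=True)
    return SpectralDataset(
        rho, row_meta, col_meta, signal_kind="depolarization_ratio"
    )


def combine_raman_fluor(
    raman: SpectralDataset,
    fluor: SpectralDataset,
    pairing: str = "by_acquisition_index",
) -> MXSpectrumSet:
    """Concatenate a Raman fingerprint dataset with its autofluorescence set.

    The fluorescence block is vector-normalized row-wise before fusion and
    its channels are tagged ``fluor-<tag>`` so every output column maps back
    to a unique (channel, wavenumber) pair.
    """
    norms = np.linalg.norm(fluor.matrix, axis=1)
    if np.any(norms == 0.0):
        raise DegenerateInputError("all-zero autofluorescence row cannot be normalized")
    fl = fluor.copy()
    fl.matrix = fluor.matrix / norms[:, None]
    fl.col_meta["channel"] = [
        t if str(t).startswith("fluor-") else f"fluor-{t}"
        for t in fl.col_meta["channel"]
    ]
    fl.signal_kind = "autofluorescence"
    return concatenate([raman, fl], pairing=pairing)
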