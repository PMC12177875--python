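"""Reading, writing and aligning Raman spectra and spectral datasets.

A :class:`Spectrum` is a single acquisition: a strictly increasing wavenumber
axis (cm^-1), one intensity per axis point, and acquisition metadata
(excitation wavelength, polarization state, signal kind, sample/class tags).
A :class:`SpectralDataset` is the aligned matrix view used by every downstream
stage: one row per spectrum, one column per (channel, wavenumber) variable.

On disk, spectra are two-column text files (wavenumber, intensity; ``#``
comments; tab/comma/whitespace delimiters) and datasets are plain CSV with a
two-row header — row 1 carries the channel tag of each variable column, row 2
its wavenumber — preceded by three metadata columns
(``class_label``, ``sample_id``, ``acquisition_index``).
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    DatasetFormatError,
    InvalidInputError,
    MetadataConflictError,
    OutOfRangeError,
    SpectrumParseError,
)

POLARIZATIONS = ("unpolarized", "parallel", "perpendicular")
SIGNAL_KINDS = ("raman", "autofluorescence", "depolarization_ratio")

META_COLUMNS = ("class_label", "sample_id", "acquisition_index")


@dataclass
class Spectrum:
    """One spectral acquisition on a strictly increasing wavenumber axis."""

    axis: np.ndarray
    intensities: np.ndarray
    excitation_nm: float | None = None
    polarization: str = "unpolarized"
    signal_kind: str = "raman"
    sample_id: str = ""
    class_label: str = ""
    acquisition_index: int = 0

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.axis.ndim != 1 or self.intensities.ndim != 1:
            raise InvalidInputError("axis and intensities must be 1-D")
        if self.axis.size != self.intensities.size:
            raise InvalidInputError("axis and intensities lengths differ")
        if self.axis.size < 2:
            raise InvalidInputError("a spectrum needs at least 2 points")
        if not np.all(np.diff(self.axis) > 0):
            raise InvalidInputError("axis must be strictly increasing")
        if self.polarization not in POLARIZATIONS:
            raise InvalidInputError(f"unknown polarization {self.polarization!r}")
        if self.signal_kind not in SIGNAL_KINDS:
            raise InvalidInputError(f"unknown signal kind {self.signal_kind!r}")

    @property
    def channel(self) -> str:
        """Channel tag combining excitation, polarization and signal kind."""
        base = f"{self.excitation_nm:g}nm" if self.excitation_nm else "na"
        if self.polarization == "parallel":
            base += "-par"
        elif self.polarization == "perpendicular":
            base += "-perp"
        if self.signal_kind == "autofluorescence":
            base = f"fluor-{base}"
        elif self.signal_kind == "depolarization_ratio":
            base = f"rho-{base}"
        return base

    def with_values(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with new intensities on the same axis."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))


@dataclass
class SpectralDataset:
    """Aligned spectra matrix with per-row labels and a per-column channel map.

    ``row_meta`` has one row per spectrum with at least ``class_label``,
    ``sample_id`` and ``acquisition_index``; ``col_meta`` has one row per
    variable with ``channel`` and ``wavenumber``.  Wavenumbers are strictly
    increasing within each contiguous channel block.
    """

    matrix: np.ndarray
    row_meta: pd.DataFrame
    col_meta: pd.DataFrame
    signal_kind: str = "raman"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise InvalidInputError("dataset matrix must be 2-D")
        if len(self.row_meta) != self.matrix.shape[0]:
            raise InvalidInputError("row_meta length does not match matrix")
        if len(self.col_meta) != self.matrix.shape[1]:
            raise InvalidInputError("col_meta length does not match matrix")
        for col in META_COLUMNS:
            if col not in self.row_meta.columns:
                raise InvalidInputError(f"row_meta misses column {col!r}")
        for col in ("channel", "wavenumber"):
            if col not in self.col_meta.columns:
                raise InvalidInputError(f"col_meta misses column {col!r}")
        self.row_meta = self.row_meta.reset_index(drop=True)
        self.col_meta = self.col_meta.reset_index(drop=True)
        _check_sample_classes(self.row_meta)
        for _, sl in self.channel_blocks():
            wn = self.col_meta["wavenumber"].to_numpy()[sl]
            if not np.all(np.diff(wn) > 0):
                raise InvalidInputError(
                    "wavenumbers must be strictly increasing within a channel block"
                )

    # -- basic views ---------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    @property
    def labels(self) -> np.ndarray:
        return self.row_meta["class_label"].to_numpy()

    @property
    def classes(self) -> list[str]:
        return sorted(self.row_meta["class_label"].unique())

    def channel_blocks(self) -> list[tuple[str, slice]]:
        """Contiguous runs of equal channel tag, in column order."""
        tags = self.col_meta["channel"].to_numpy()
        blocks: list[tuple[str, slice]] = []
        start = 0
        for i in range(1, len(tags) + 1):
            if i == len(tags) or tags[i] != tags[start]:
                blocks.append((str(tags[start]), slice(start, i)))
                start = i
        return blocks

    @classmethod
    def _unchecked(cls, matrix, row_meta, col_meta, signal_kind) -> "SpectralDataset":
        """Construct without re-validating invariants.

        Used for derived views (barcode subsets reorder columns, so the
        within-block monotonicity invariant no longer applies).
        """
        ds = cls.__new__(cls)
        ds.matrix = matrix
        ds.row_meta = row_meta.reset_index(drop=True)
        ds.col_meta = col_meta.reset_index(drop=True)
        ds.signal_kind = signal_kind
        return ds

    def select_columns(self, indices: np.ndarray | list[int]) -> "SpectralDataset":
        """Column subset in the given order (used by barcode application)."""
        indices = np.asarray(indices, dtype=int)
        return SpectralDataset._unchecked(
            self.matrix[:, indices],
            self.row_meta.copy(),
            self.col_meta.iloc[indices].copy(),
            self.signal_kind,
        )

    def subset_rows(self, indices: np.ndarray | list[int]) -> "SpectralDataset":
        """Row subset in the given order, preserving the column map."""
        indices = np.asarray(indices, dtype=int)
        return SpectralDataset._unchecked(
            self.matrix[indices],
            self.row_meta.iloc[indices].copy(),
            self.col_meta.copy(),
            self.signal_kind,
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset._unchecked(
            self.matrix.copy(),
            self.row_meta.copy(),
            self.col_meta.copy(),
            self.signal_kind,
        )


def _check_sample_classes(row_meta: pd.DataFrame) -> None:
    if len(row_meta) == 0:
        return
    per_sample = row_meta.groupby("sample_id")["class_label"].nunique()
    bad = per_sample[per_sample > 1]
    if len(bad):
        raise MetadataConflictError(
            f"samples with conflicting class labels: {list(bad.index)}"
        )


# ---------------------------------------------------------------------------
# spectrum files
# ---------------------------------------------------------------------------

def read_spectrum(path, **meta) -> Spectrum:
    """Read a two-column (wavenumber, intensity) text spectrum file.

    Accepts tab, comma or whitespace delimiters and ``#`` comment lines.
    Descending-axis instrument exports are silently reordered to ascending.
    Keyword arguments become spectrum metadata (``sample_id``,
    ``class_label``, ``excitation_nm``, ...).
    """
    axis: list[float] = []
    vals: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(",") if "," in stripped else stripped.split()
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                axis.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc
    if len(axis) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data points")
    order = np.argsort(np.asarray(axis), kind="stable")
    ax = np.asarray(axis)[order]
    iv = np.asarray(vals)[order]
    if np.any(np.diff(ax) == 0):
        raise SpectrumParseError(f"{path}: duplicate wavenumber values")
    return Spectrum(ax, iv, **meta)


def resample_to_axis(s: Spectrum, target_axis) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target_axis`` (no extrapolation)."""
    target = np.asarray(target_axis, dtype=float)
    if target.ndim != 1 or target.size < 1:
        raise InvalidInputError("target axis must be a non-empty 1-D array")
    if target.size > 1 and not np.all(np.diff(target) > 0):
        raise InvalidInputError("target axis must be strictly increasing")
    if target[0] < s.axis[0] or target[-1] > s.axis[-1]:
        raise OutOfRangeError(
            f"target axis [{target[0]:g}, {target[-1]:g}] outside source "
            f"range [{s.axis[0]:g}, {s.axis[-1]:g}]"
        )
    values = np.interp(target, s.axis, s.intensities)
    return replace(s, axis=target, intensities=values)


def assemble_dataset(spectra: list[Spectrum]) -> SpectralDataset:
    """Align spectra onto a shared axis and stack them into a dataset.

    All spectra must share signal kind and channel.  The target axis is the
    densest member's axis restricted to the intersection of all axis ranges;
    rows are ordered by (class_label, sample_id, acquisition_index), so the
    result is invariant to the input ordering.
    """
    if not spectra:
        raise InvalidInputError("no spectra to assemble")
    kinds = {s.signal_kind for s in spectra}
    if len(kinds) > 1:
        raise InvalidInputError(f"mixed signal kinds: {sorted(kinds)}")
    channels = {s.channel for s in spectra}
    if len(channels) > 1:
        raise InvalidInputError(f"mixed channels: {sorted(channels)}")

    lo = max(s.axis[0] for s in spectra)
    hi = min(s.axis[-1] for s in spectra)
    if lo >= hi:
        raise AlignmentError("spectrum axes do not overlap")
    densest = max(spectra, key=lambda s: s.axis.size)
    mask = (densest.axis >= lo) & (densest.axis <= hi)
    target = densest.axis[mask]
    if target.size < 2:
        raise AlignmentError("axis intersection has fewer than 2 points")

    ordered = sorted(
        spectra, key=lambda s: (s.class_label, s.sample_id, s.acquisition_index)
    )
    rows = [resample_to_axis(s, target).intensities for s in ordered]
    row_meta = pd.DataFrame(
        {
            "class_label": [s.class_label for s in ordered],
            "sample_id": [s.sample_id for s in ordered],
            "acquisition_index": [s.acquisition_index for s in ordered],
        }
    )
    col_meta = pd.DataFrame(
        {"channel": [ordered[0].channel] * target.size, "wavenumber": target}
    )
    return SpectralDataset(
        np.vstack(rows), row_meta, col_meta, signal_kind=spectra[0].signal_kind
    )


# ---------------------------------------------------------------------------
# dataset files
# ---------------------------------------------------------------------------

def write_dataset(d: SpectralDataset, path) -> None:
    """Write a dataset as CSV with the two-row channel/wavenumber header."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(META_COLUMNS) + list(d.col_meta["channel"]))
        writer.writerow(
            ["", "", ""] + [format(w, ".17g") for w in d.col_meta["wavenumber"]]
        )
        for i in range(d.n_spectra):
            meta = [
                str(d.row_meta.at[i, "class_label"]),
                str(d.row_meta.at[i, "sample_id"]),
                str(d.row_meta.at[i, "acquisition_index"]),
            ]
            writer.writerow(meta + [format(v, ".17g") for v in d.matrix[i]])


def read_dataset(path, signal_kind: str = "raman") -> SpectralDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round-trip)."""
    with open(path, "r", encoding="utf-8") as fh:
        header1 = fh.readline()
        header2 = fh.readline()
        if not header1 or not header2:
            raise DatasetFormatError(f"{path}: truncated header")
        row1 = next(csv.reader(io.StringIO(header1)))
        row2 = next(csv.reader(io.StringIO(header2)))
        if tuple(row1[:3]) != META_COLUMNS:
            raise DatasetFormatError(
                f"{path}: header must start with {','.join(META_COLUMNS)}"
            )
        if len(row1) != len(row2):
            raise DatasetFormatError(f"{path}: header rows have different widths")
        channels = row1[3:]
        try:
            wavenumbers = [float(w) for w in row2[3:]]
        except ValueError as exc:
            raise DatasetFormatError(f"{path}: non-numeric wavenumber header") from exc

        n_vars = len(channels)
        labels: list[str] = []
        samples: list[str] = []
        acq: list[int] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(csv.reader(fh), start=3):
            if not rec:
                continue
            if len(rec) != n_vars + 3:
                raise DatasetFormatError(
                    f"{path}: line {lineno}: expected {n_vars + 3} fields, "
                    f"got {len(rec)}"
                )
            labels.append(rec[0])
            samples.append(rec[1])
            try:
                acq.append(int(rec[2]))
                rows.append([float(v) for v in rec[3:]])
            except ValueError as exc:
                raise DatasetFormatError(
                    f"{path}: line {lineno}: non-numeric value"
                ) from exc

    matrix = (
        np.asarray(rows, dtype=float) if rows else np.empty((0, n_vars))
    )
    row_meta = pd.DataFrame(
        {"class_label": labels, "sample_id": samples, "acquisition_index": acq},
        dtype=object,
    )
    row_meta["acquisition_index"] = row_meta["acquisition_index"].astype(int)
    col_meta = pd.DataFrame({"channel": channels, "wavenumber": wavenumbers})
    return SpectralDataset(matrix, row_meta, col_meta, signal_kind=signal_kind)
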