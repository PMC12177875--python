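"""Synthetic multi-channel Raman-like dataset generator.

The generator emulates the statistical structure the barcoding method
assumes: a 5-class design (one control plus four disease-like classes)
with 3 samples per class and 30 spectra per sample (450 spectra per
channel), acquired in two excitation channels whose peak amplitudes differ
— mimicking resonance/preresonance enhancement of selected vibrational
modes in the shorter-wavelength channel.

Each raw spectrum is a sum of Lorentzian peaks (a shared molecular
backbone plus class-specific peaks tagged with the channel(s) carrying the
difference), a broad autofluorescence-like baseline (low-order polynomial
plus a wide Gaussian hump, randomly rescaled per spectrum), multiplicative
lognormal sample-level amplitude effects, and additive white Gaussian
detector noise.  Blank (substrate) spectra contain only the baseline and
noise.  A ground-truth record lists, per class, the planted variables and
their expected direction, for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .spectral_io import SpectralDataset, Spectrum


@dataclass
class PeakSpec:
    """One Lorentzian band: center/FWHM in cm^-1, amplitude per channel."""

    center: float
    fwhm: float
    amplitude: dict[str, float]
    rho: float = 0.3  # depolarization ratio for polarized variants

    def validate(self) -> None:
        if self.fwhm <= 0:
            raise InvalidConfigError("peak FWHM must be > 0")
        if any(a < 0 for a in self.amplitude.values()):
            raise InvalidConfigError("peak amplitudes must be >= 0")
        if self.rho < 0:
            raise InvalidConfigError("depolarization ratio must be >= 0")


@dataclass
class SyntheticDesign:
    """Full specification of a synthetic multi-channel study."""

    backbone: list[PeakSpec]
    class_peaks: dict[str, list[PeakSpec]]  # class -> extra peaks
    axes: dict[str, tuple[float, float, int]]  # channel -> (lo, hi, n_points)
    n_samples_per_class: int = 3
    n_spectra_per_sample: int = 30
    sample_effect_sd: float = 0.08  # lognormal sigma, per (sample, peak)
    spectrum_effect_sd: float = 0.08  # lognormal sigma, per (spectrum, peak)
    noise_sd: float = 0.02  # additive Gaussian, per point
    baseline_amplitude: float = 5.0
    baseline_scale_sd: float = 0.1  # lognormal sigma of per-spectrum scale
    n_blanks: int = 3
    polarized: bool = False
    seed: int = 1234

    def validate(self) -> None:
        if self.n_spectra_per_sample < 4:
            raise InvalidConfigError("need at least 4 spectra per sample")
        if self.n_samples_per_class < 1:
            raise InvalidConfigError("need at least 1 sample per class")
        if not self.class_peaks:
            raise InvalidConfigError("no classes defined")
        for lo, hi, n in self.axes.values():
            if n < 64:
                raise InvalidConfigError("axis must have at least 64 points")
            if hi <= lo:
                raise InvalidConfigError("axis range must be increasing")
        for peak in self.backbone:
            peak.validate()
        for peaks in self.class_peaks.values():
            for peak in peaks:
                peak.validate()
        if min(self.noise_sd, self.sample_effect_sd, self.spectrum_effect_sd) < 0:
            raise InvalidConfigError("noise/effect sd must be >= 0")

    @property
    def classes(self) -> list[str]:
        return sorted(self.class_peaks)


@dataclass
class PlantedFeature:
    """Ground truth for one class-specific peak in one channel."""

    class_label: str
    channel: str
    center: float
    center_column: int
    window_columns: np.ndarray  # columns within +-FWHM of the center
    direction: int  # +1: intensity increases in this class


@dataclass
class GenerationResult:
    channels: dict[str, SpectralDataset]  # raw, unprocessed
    blanks: dict[str, list[Spectrum]]
    truth: list[PlantedFeature]
    polarized: dict[str, dict[str, SpectralDataset]] = field(default_factory=dict)

    def truth_for(self, class_label: str) -> list[PlantedFeature]:
        return [t for t in self.truth if t.class_label == class_label]

    def truth_records(self) -> list[dict]:
        return [
            {
                "class_label": t.class_label,
                "channel": t.channel,
                "center": float(t.center),
                "center_column": int(t.center_column),
                "window_columns": [int(c) for c in t.window_columns],
                "direction": int(t.direction),
            }
            for t in self.truth
        ]


def design_to_dict(design: SyntheticDesign) -> dict:
    """JSON-serializable form of a design (inverse of :func:`design_from_dict`)."""

    def peaks(ps: list[PeakSpec]) -> list[dict]:
        return [
            {
                "center": p.center,
                "fwhm": p.fwhm,
                "amplitude": dict(p.amplitude),
                "rho": p.rho,
            }
            for p in ps
        ]

    return {
        "backbone": peaks(design.backbone),
        "class_peaks": {c: peaks(ps) for c, ps in design.class_peaks.items()},
        "axes": {ch: list(ax) for ch, ax in design.axes.items()},
        "n_samples_per_class": design.n_samples_per_class,
        "n_spectra_per_sample": design.n_spectra_per_sample,
        "sample_effect_sd": design.sample_effect_sd,
        "spectrum_effect_sd": design.spectrum_effect_sd,
        "noise_sd": design.noise_sd,
        "baseline_amplitude": design.baseline_amplitude,
        "baseline_scale_sd": design.baseline_scale_sd,
        "n_blanks": design.n_blanks,
        "polarized": design.polarized,
        "seed": design.seed,
    }


def design_from_dict(data: dict) -> SyntheticDesign:
    """Build a design from its JSON form; unknown keys are rejected."""
    known = {
        "backbone",
        "class_peaks",
        "axes",
        "n_samples_per_class",
        "n_spectra_per_sample",
        "sample_effect_sd",
        "spectrum_effect_sd",
        "noise_sd",
        "baseline_amplitude",
        "baseline_scale_sd",
        "n_blanks",
        "polarized",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise InvalidConfigError(f"unknown design keys: {sorted(unknown)}")

    def peaks(records: list[dict]) -> list[PeakSpec]:
        return [
            PeakSpec(
                center=float(r["center"]),
                fwhm=float(r["fwhm"]),
                amplitude={k: float(v) for k, v in r["amplitude"].items()},
                rho=float(r.get("rho", 0.3)),
            )
            for r in records
        ]

    design = SyntheticDesign(
        backbone=peaks(data.get("backbone", [])),
        class_peaks={c: peaks(ps) for c, ps in data["class_peaks"].items()},
        axes={
            ch: (float(lo), float(hi), int(n))
            for ch, (lo, hi, n) in data["axes"].items()
        },
        n_samples_per_class=int(data.get("n_samples_per_class", 3)),
        n_spectra_per_sample=int(data.get("n_spectra_per_sample", 30)),
        sample_effect_sd=float(data.get("sample_effect_sd", 0.08)),
        spectrum_effect_sd=float(data.get("spectrum_effect_sd", 0.08)),
        noise_sd=float(data.get("noise_sd", 0.02)),
        baseline_amplitude=float(data.get("baseline_amplitude", 5.0)),
        baseline_scale_sd=float(data.get("baseline_scale_sd", 0.1)),
        n_blanks=int(data.get("n_blanks", 3)),
        polarized=bool(data.get("polarized", False)),
        seed=int(data.get("seed", 1234)),
    )
    design.validate()
    return design


def _lorentzian(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    gamma = fwhm / 2.0
    return gamma**2 / ((x - center) ** 2 + gamma**2)


def _baseline_shape(x: np.ndarray) -> np.ndarray:
    """Fixed broad baseline: gentle tilt plus a wide Gaussian hump."""
    span = x[-1] - x[0]
    mid = x[0] + 0.45 * span
    t = (x - x[0]) / span
    hump = np.exp(-0.5 * ((x - mid) / (span / 3.0)) ** 2)
    return 0.6 + 0.25 * t - 0.1 * t**2 + hump


def generate(design: SyntheticDesign, seed: int | None = None) -> GenerationResult:
    """Generate raw per-channel datasets, blanks and the truth record.

    Deterministic for a given seed (``design.seed`` unless overridden):
    identical seeds give bit-identical datasets.
    """
    design.validate()
    rng = np.random.default_rng(design.seed if seed is None else seed)
    channels = sorted(design.axes)
    axes = {
        ch: np.linspace(lo, hi, n)
        for ch, (lo, hi, n) in sorted(design.axes.items())
    }

    classes = design.classes
    # sample-level lognormal amplitude multipliers, one per (sample, peak);
    # shared across channels so a sample's composition is channel-independent
    sample_ids = {
        c: [f"{c}-S{i + 1}" for i in range(design.n_samples_per_class)]
        for c in classes
    }
    multipliers: dict[tuple[str, str, int], float] = {}
    for c in classes:
        peaks = design.backbone + design.class_peaks[c]
        for sid in sample_ids[c]:
            for pi in range(len(peaks)):
                multipliers[(c, sid, pi)] = float(
                    rng.lognormal(mean=0.0, sigma=design.sample_effect_sd)
                )

    out_channels: dict[str, SpectralDataset] = {}
    out_blanks: dict[str, list[Spectrum]] = {}
    polarized: dict[str, dict[str, SpectralDataset]] = {}
    for ch in channels:
        x = axes[ch]
        base = _baseline_shape(x)
        rows, rows_par, rows_perp = [], [], []
        labels, samples, acq = [], [], []
        for c in classes:
            peaks = design.backbone + design.class_peaks[c]
            shapes = np.vstack(
                [_lorentzian(x, p.center, p.fwhm) for p in peaks]
            )
            amps = np.array([p.amplitude.get(ch, 0.0) for p in peaks])
            rhos = np.array([p.rho for p in peaks])
            for sid in sample_ids[c]:
                mult = np.array(
                    [multipliers[(c, sid, pi)] for pi in range(len(peaks))]
                )
                sample_eff = amps * mult
                for a in range(design.n_spectra_per_sample):
                    # spot-to-spot compositional heterogeneity of the dried
                    # droplet: each acquisition samples the peaks differently
                    jitter = rng.lognormal(
                        mean=0.0, sigma=design.spectrum_effect_sd, size=len(peaks)
                    )
                    eff = sample_eff * jitter
                    clean = eff @ shapes
                    scale = rng.lognormal(mean=0.0, sigma=design.baseline_scale_sd)
                    noise = rng.normal(0.0, design.noise_sd, size=x.size)
                    rows.append(clean + design.baseline_amplitude * scale * base + noise)
                    if design.polarized:
                        par = (eff / (1.0 + rhos)) @ shapes
                        perp = (eff * rhos / (1.0 + rhos)) @ shapes
                        bl = design.baseline_amplitude * scale * base
                        rows_par.append(
                            par + 0.5 * bl + rng.normal(0.0, design.noise_sd, x.size)
                        )
                        rows_perp.append(
                            perp + 0.5 * bl + rng.normal(0.0, design.noise_sd, x.size)
                        )
                    labels.append(c)
                    samples.append(sid)
                    acq.append(a)
        row_meta = pd.DataFrame(
            {"class_label": labels, "sample_id": samples, "acquisition_index": acq}
        )
        col_meta = pd.DataFrame({"channel": [ch] * x.size, "wavenumber": x})
        out_channels[ch] = SpectralDataset(np.vstack(rows), row_meta, col_meta)
        if design.polarized:
            par_cols = col_meta.copy()
            par_cols["channel"] = f"{ch}-par"
            perp_cols = col_meta.copy()
            perp_cols["channel"] = f"{ch}-perp"
            polarized[ch] = {
                "parallel": SpectralDataset(
                    np.vstack(rows_par), row_meta.copy(), par_cols
                ),
                "perpendicular": SpectralDataset(
                    np.vstack(rows_perp), row_meta.copy(), perp_cols
                ),
            }
        blanks = []
        for bi in range(design.n_blanks):
            scale = rng.lognormal(mean=0.0, sigma=design.baseline_scale_sd)
            noise = rng.normal(0.0, design.noise_sd, size=x.size)
            blanks.append(
                Spectrum(
                    x,
                    design.baseline_amplitude * scale * base + noise,
                    sample_id=f"blank-{bi + 1}",
                    class_label="__blank__",
                    acquisition_index=bi,
                )
            )
        out_blanks[ch] = blanks

    truth: list[PlantedFeature] = []
    for c in classes:
        for peak in design.class_peaks[c]:
            for ch in channels:
                if peak.amplitude.get(ch, 0.0) <= 0:
                    continue
                x = axes[ch]
                center_col = int(np.argmin(np.abs(x - peak.center)))
                window = np.nonzero(np.abs(x - peak.center) <= peak.fwhm)[0]
                truth.append(
                    PlantedFeature(
                        class_label=c,
                        channel=ch,
                        center=peak.center,
                        center_column=center_col,
                        window_columns=window,
                        direction=+1,
                    )
                )
    return GenerationResult(
        channels=out_channels, blanks=out_blanks, truth=truth, polarized=polarized
    )


def paper_like_design(
    n_points: int = 1024,
    n_samples_per_class: int = 3,
    n_spectra_per_sample: int = 30,
    effect_scale: float = 1.0,
    seed: int = 1234,
    polarized: bool = False,
) -> SyntheticDesign:
    """Default 5-class, two-channel study design.

    Classes: a control carrying only the shared backbone; ``diseaseA`` with
    extra peaks only in the 532 nm channel (resonance-enhanced modes);
    ``diseaseB`` only in the 785 nm channel; ``diseaseC`` and ``diseaseD``
    with small overlapping effects in both channels at shared centers
    (amplitude ratios swapped), deliberately the hardest pair.

    ``effect_scale`` multiplies every class-specific amplitude (used by
    effect-size sweeps); the axis covers the 600-1750 cm^-1 fingerprint
    window in both channels.
    """
    ch1, ch2 = "532nm", "785nm"
    axes = {ch1: (600.0, 1750.0, n_points), ch2: (600.0, 1750.0, n_points)}
    backbone = [
        PeakSpec(747.0, 14.0, {ch1: 0.90, ch2: 0.25}),
        PeakSpec(880.0, 16.0, {ch1: 0.70, ch2: 0.50}),
        PeakSpec(971.0, 12.0, {ch1: 0.50, ch2: 0.20}),
        PeakSpec(1003.0, 10.0, {ch1: 0.30, ch2: 1.00}),
        PeakSpec(1126.0, 14.0, {ch1: 0.40, ch2: 0.50}),
        PeakSpec(1260.0, 20.0, {ch1: 0.30, ch2: 0.70}),
        PeakSpec(1308.0, 16.0, {ch1: 0.60, ch2: 0.40}),
        PeakSpec(1367.0, 14.0, {ch1: 0.80, ch2: 0.15}),
        PeakSpec(1440.0, 18.0, {ch1: 0.35, ch2: 0.90}),
        PeakSpec(1587.0, 14.0, {ch1: 0.85, ch2: 0.30}),
        PeakSpec(1620.0, 12.0, {ch1: 0.50, ch2: 0.25}),
        PeakSpec(1660.0, 22.0, {ch1: 0.40, ch2: 1.00}),
    ]
    # class-specific marker bands sit at centers distinct from the backbone
    # (disease-specific modes, e.g. aggregation-related shifts), three per
    # single-channel class to mirror the three-region barcode structure
    e = effect_scale
    class_peaks = {
        "control": [],
        "diseaseA": [
            PeakSpec(940.0, 10.0, {ch1: 0.45 * e, ch2: 0.0}),
            PeakSpec(1045.0, 10.0, {ch1: 0.45 * e, ch2: 0.0}),
            PeakSpec(1525.0, 10.0, {ch1: 0.45 * e, ch2: 0.0}),
        ],
        "diseaseB": [
            PeakSpec(820.0, 10.0, {ch1: 0.0, ch2: 0.45 * e}),
            PeakSpec(1235.0, 10.0, {ch1: 0.0, ch2: 0.45 * e}),
            PeakSpec(1700.0, 10.0, {ch1: 0.0, ch2: 0.45 * e}),
        ],
        "diseaseC": [
            PeakSpec(1160.0, 10.0, {ch1: 0.25 * e, ch2: 0.16 * e}),
            PeakSpec(1490.0, 10.0, {ch1: 0.16 * e, ch2: 0.25 * e}),
        ],
        "diseaseD": [
            PeakSpec(1160.0, 10.0, {ch1: 0.16 * e, ch2: 0.25 * e}),
            PeakSpec(1490.0, 10.0, {ch1: 0.25 * e, ch2: 0.16 * e}),
        ],
    }
    return SyntheticDesign(
        backbone=backbone,
        class_peaks=class_peaks,
        axes=axes,
        n_samples_per_class=n_samples_per_class,
        n_spectra_per_sample=n_spectra_per_sample,
        seed=seed,
        polarized=polarized,
    )
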