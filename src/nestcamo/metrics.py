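"""Achromatic camouflage metrics: luminance channels, mean luminance and
contrast, 32-level luminance histograms, and FFT bandpass pattern-energy
spectra.

The relative metrics are L1 distances between a target region (egg clutch
or incubating adult) and its background: ``luminance_diff`` compares
pixel-proportion histograms at 32 linear luminance levels; ``pattern_diff``
compares granularity spectra — the standard deviation of bandpass-filtered
luminance at 17 spatial scales from 2 px to 512 px in steps of √2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vision import ConeCatchImage, VisualSystem

__all__ = [
    "LuminanceImage",
    "PatternSpectrum",
    "luminance_image",
    "mean_luminance",
    "contrast",
    "luminance_histogram",
    "luminance_diff",
    "bandpass_bank",
    "pattern_spectrum",
    "pattern_diff",
]

N_LUM_BINS = 32
SQRT2 = np.sqrt(2.0)


@dataclass
class LuminanceImage:
    """Single achromatic channel as seen by one visual system."""

    values: np.ndarray
    system_name: str = ""
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("luminance values must be finite")
        if np.any(self.values < 0):
            raise ValueError("luminance values must be non-negative")


@dataclass
class PatternSpectrum:
    """Granularity spectrum: pattern energy (SD of bandpass-filtered
    luminance within the region) at each spatial scale in px."""

    scales: np.ndarray
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.scales = np.asarray(self.scales, dtype=float)
        self.energies = np.asarray(self.energies, dtype=float)
        if self.scales.shape != self.energies.shape:
            raise ValueError("scales and energies differ in length")
        if np.any(self.energies < -1e-12):
            raise ValueError("energies must be non-negative")


def luminance_image(cone: ConeCatchImage,
                    system: VisualSystem | None = None) -> LuminanceImage:
    """Extract the luminance channel a visual system perceives.

    Ferret: the L cone image. Human: pixelwise (L+M)/2. Peafowl: the
    double-cone image. The rule itself lives on the VisualSystem.
    """
    system = cone.system if system is None else system
    names = system.luminance_channels
    missing = [n for n in names if n not in cone.channels]
    if missing:
        raise ValueError(f"cone image lacks luminance channel(s) {missing}")
    values = np.mean([cone.channels[n] for n in names], axis=0)
    return LuminanceImage(values=np.clip(values, 0.0, None),
                          system_name=system.name,
                          px_per_mm=cone.px_per_mm)


def _masked(lum: LuminanceImage | np.ndarray, mask: np.ndarray) -> np.ndarray:
    values = lum.values if isinstance(lum, LuminanceImage) else np.asarray(lum)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return values[mask]


def mean_luminance(lum, mask) -> float:
    """Mean of square-root-transformed luminance over the region."""
    return float(np.sqrt(_masked(lum, mask)).mean())


def contrast(lum, mask) -> float:
    """Population SD of square-root-transformed luminance over the region."""
    px = _masked(lum, mask)
    if px.size < 2:
        raise ValueError("contrast needs at least 2 pixels")
    return float(np.sqrt(px).std())


def luminance_histogram(lum, mask) -> np.ndarray:
    """Pixel proportions at 32 linear luminance levels over [0%, 100%].

    Values above 100% reflectance fall in the top bin. Proportions sum
    to 1, so regions of unequal area compare fairly.
    """
    px = _masked(lum, mask)
    idx = np.minimum((px * N_LUM_BINS).astype(int), N_LUM_BINS - 1)
    counts = np.bincount(idx, minlength=N_LUM_BINS).astype(float)
    return counts / counts.sum()


def luminance_diff(target_hist: np.ndarray, background_hist: np.ndarray
                   ) -> float:
    """L1 distance between two 32-bin luminance histograms (range [0, 2])."""
    t = np.asarray(target_hist, dtype=float)
    b = np.asarray(background_hist, dtype=float)
    if t.shape != b.shape:
        raise ValueError("histograms differ in length")
    return float(np.abs(t - b).sum())


def bandpass_bank(max_scale_px: float = 512.0) -> np.ndarray:
    """Spatial scales 2·(√2)^k px up to ``max_scale_px``.

    The default top scale of 512 px gives exactly 17 scales.
    """
    if max_scale_px < 2:
        raise ValueError("max scale must be at least 2 px")
    n = int(np.floor(np.log(max_scale_px / 2.0) / np.log(SQRT2) + 1e-9)) + 1
    # 2^(1 + k/2) keeps the even-index scales (2, 4, 8, ...) exact so band
    # edges fall where integer-period signals expect them
    return 2.0 ** (1.0 + np.arange(n) / 2.0)


def _period_map(shape: tuple[int, int]) -> np.ndarray:
    """Spatial period (px) of each FFT coefficient; DC maps to +inf."""
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    freq = np.hypot(fy, fx)
    with np.errstate(divide="ignore"):
        return np.where(freq > 0, 1.0 / freq, np.inf)


def pattern_spectrum(lum, mask, max_scale_px: float = 512.0
                     ) -> PatternSpectrum:
    """Granularity spectrum of a masked region.

    The mask's bounding box is cropped, pixels outside the mask are
    replaced by the region mean (no windowing), and for each scale s an
    annular FFT bandpass keeps spatial periods in [s, s·√2). The energy at
    s is the standard deviation of the filtered values over the mask.
    Scales whose band lies beyond the crop contribute zero energy, so all
    spectra share the same scale list.
    """
    values = lum.values if isinstance(lum, LuminanceImage) else np.asarray(lum)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size < 4 or cols.size < 4:
        raise ValueError("region bounding box smaller than 4×4 px")
    crop = values[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].copy()
    cmask = mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    region_mean = crop[cmask].mean()
    crop[~cmask] = region_mean

    spectrum = np.fft.fft2(crop)
    periods = _period_map(crop.shape)
    scales = bandpass_bank(max_scale_px)
    # consecutive scales as band edges: bands partition the period axis
    edges = np.append(scales, scales[-1] * SQRT2)
    energies = np.empty_like(scales)
    for i in range(len(scales)):
        band = (periods >= edges[i]) & (periods < edges[i + 1])
        if not band.any():
            energies[i] = 0.0
            continue
        filtered = np.fft.ifft2(np.where(band, spectrum, 0)).real
        energies[i] = filtered[cmask].std()
    return PatternSpectrum(scales=scales, energies=energies)


def pattern_diff(spec_t: PatternSpectrum, spec_b: PatternSpectrum) -> float:
    """Sum over scales of |target energy − background energy|."""
    if (spec_t.scales.shape != spec_b.scales.shape
            or not np.allclose(spec_t.scales, spec_b.scales)):
        raise ValueError("pattern spectra use different scale lists")
    return float(np.abs(spec_t.energies - spec_b.energies).sum())
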