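"""Camera calibration: linearization, reflectance normalization, saturation
rescaling, UV/visible alignment and scale matching.

Raw camera counts are non-linear in scene radiance. A monotone power-law
response is fitted per channel from photographed Spectralon reflectance
standards, pixel values are normalized against a grey standard of known
reflectance (default 40%), and images whose brightest pixel exceeds 100%
reflectance are rescaled so the full dynamic range survives 16-bit storage
(the scale factor is kept so floating-point processing can undo it).
UV-pass and visible-pass exposures of the same scene are registered with a
uniform scale-plus-translation transform before being stacked into a single
five-channel reflectance image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

__all__ = [
    "RawImageSet",
    "MultispectralImage",
    "RegionSet",
    "LinearizationModel",
    "fit_linearization",
    "normalize_to_reflectance",
    "rescale_saturation",
    "reconstruct_reflectance",
    "align_uv_visible",
    "resize_to_scale",
]

MAX_COUNT = 65535
CHANNEL_NAMES = ("vis_r", "vis_g", "vis_b", "uv_r", "uv_b")


class CalibrationError(ValueError):
    """Raised when calibration inputs are degenerate (bad standards, zero
    standard response, failed alignment)."""


@dataclass
class RawImageSet:
    """Unprocessed 16-bit counts for one scene: three visible channels and
    the red/blue channels photographed through the UV-pass filter."""

    vis_channels: np.ndarray          # (3, H, W) uint16 counts
    uv_channels: np.ndarray           # (2, H, W) uint16 counts
    standard_region: np.ndarray       # bool mask over grey-standard pixels
    standard_reflectance: float = 0.40
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        self.vis_channels = np.asarray(self.vis_channels)
        self.uv_channels = np.asarray(self.uv_channels)
        self.standard_region = np.asarray(self.standard_region, dtype=bool)
        if self.vis_channels.shape[0] != 3 or self.uv_channels.shape[0] != 2:
            raise ValueError("expected 3 visible and 2 UV channels")
        if self.vis_channels.shape[1:] != self.uv_channels.shape[1:]:
            raise ValueError("visible and UV channel shapes differ")
        if not self.standard_region.any():
            raise ValueError("standard_region is empty")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")


@dataclass
class MultispectralImage:
    """Aligned five-channel reflectance stack (vis R/G/B + UV R/B).

    Values are fractions of a perfect diffuse reflector and may exceed 1;
    ``saturation_scale`` records the factor applied by the saturation rule
    so that 16-bit storage round-trips.
    """

    channels: np.ndarray              # (5, H, W) float
    px_per_mm: float = 1.0
    saturation_scale: float = 1.0

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3 or self.channels.shape[0] != 5:
            raise ValueError("expected a (5, H, W) channel stack")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if not 0 < self.saturation_scale <= 1:
            raise ValueError("saturation_scale must lie in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def to_tiff(self, path: str | Path) -> None:
        """Write a 32-bit float multichannel TIFF plus a JSON sidecar with
        px_per_mm and the saturation scale."""
        path = Path(path)
        tifffile.imwrite(path, self.channels.astype(np.float32))
        sidecar = {"px_per_mm": self.px_per_mm,
                   "saturation_scale": self.saturation_scale,
                   "channel_names": list(CHANNEL_NAMES)}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_tiff(cls, path: str | Path) -> "MultispectralImage":
        path = Path(path)
        channels = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(channels=np.asarray(channels, dtype=np.float64),
                   px_per_mm=float(meta["px_per_mm"]),
                   saturation_scale=float(meta["saturation_scale"]))


@dataclass
class RegionSet:
    """Target / background / exclusion masks over one scene.

    Nonzero pixels are members. Excluded pixels are removed from both the
    target and the background before any metric sees them.
    """

    target_mask: np.ndarray
    background_mask: np.ndarray
    exclusion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.target_mask = np.asarray(self.target_mask) != 0
        self.background_mask = np.asarray(self.background_mask) != 0
        if self.exclusion_mask is None:
            self.exclusion_mask = np.zeros_like(self.target_mask)
        else:
            self.exclusion_mask = np.asarray(self.exclusion_mask) != 0
        if self.target_mask.shape != self.background_mask.shape:
            raise ValueError("mask shapes differ")
        if (self.target_mask & self.background_mask).any():
            raise ValueError("target and background masks overlap")

    @property
    def target(self) -> np.ndarray:
        return self.target_mask & ~self.exclusion_mask

    @property
    def background(self) -> np.ndarray:
        return self.background_mask & ~self.exclusion_mask


class LinearizationModel:
    """Monotone power-law-plus-offset camera linearization, one curve per
    channel, in the fit/transform idiom.

    The model per channel is ``linear = a * (count / 65535) ** g + c`` with
    ``a > 0`` and ``g > 0``, which is non-decreasing over the full count
    range. ``fit`` takes, per channel, the (reflectance, mean raw count)
    pairs measured from calibrated reflectance standards; ``transform`` maps
    raw counts to linearized responses proportional to reflectance.

    Attributes set by :meth:`fit` carry a trailing underscore:
    ``coef_`` maps channel name -> (a, g, c) and ``r_squared_`` maps channel
    name -> goodness of fit of the linearized counts against the standards'
    reflectances.
    """

    def __init__(self, min_standards: int = 4):
        self.min_standards = min_standards

    # -- sklearn-style param plumbing -------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"min_standards": self.min_standards}

    def set_params(self, **params) -> "LinearizationModel":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    # ----------------------------------------------------------------------
    @staticmethod
    def _curve(x: np.ndarray, a: float, g: float, c: float) -> np.ndarray:
        return a * np.power(np.clip(x, 0.0, None), g) + c

    def fit(self, standards: dict[str, list[tuple[float, float]]]
            ) -> "LinearizationModel":
        """Fit one monotone curve per channel.

        Parameters
        ----------
        standards
            Mapping channel name -> list of ``(reflectance, mean_count)``
            pairs, one per photographed standard. At least
            ``min_standards`` standards per channel, reflectances distinct
            and in (0, 1].
        """
        self.coef_ = {}
        self.r_squared_ = {}
        for channel, pairs in standards.items():
            refl = np.asarray([p[0] for p in pairs], dtype=float)
            counts = np.asarray([p[1] for p in pairs], dtype=float)
            if len(pairs) < self.min_standards:
                raise CalibrationError(
                    f"channel {channel!r}: {len(pairs)} standards, "
                    f"need at least {self.min_standards}")
            if len(np.unique(refl)) != len(refl) or np.any(refl <= 0) or np.any(refl > 1):
                raise CalibrationError(
                    f"channel {channel!r}: reflectances must be distinct and in (0, 1]")
            order = np.argsort(refl)
            if np.any(np.diff(counts[order]) < 0):
                raise CalibrationError(
                    f"channel {channel!r}: raw counts not monotone in reflectance")
            x = counts / MAX_COUNT
            p0 = (1.0, 2.0, 0.0)
            popt, _ = optimize.curve_fit(
                self._curve, x, refl, p0=p0, maxfev=20000,
                bounds=([1e-12, 1e-3, -0.5], [1e6, 20.0, 0.5]))
            pred = self._curve(x, *popt)
            ss_res = float(np.sum((refl - pred) ** 2))
            ss_tot = float(np.sum((refl - refl.mean()) ** 2))
            self.coef_[channel] = tuple(float(v) for v in popt)
            self.r_squared_[channel] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        return self

    def transform(self, counts: np.ndarray, channel: str) -> np.ndarray:
        """Map raw counts of one channel to linearized responses."""
        a, g, c = self.coef_[channel]
        return self._curve(np.asarray(counts, dtype=float) / MAX_COUNT, a, g, c)


def fit_linearization(standards: dict[str, list[tuple[float, float]]],
                      min_standards: int = 4) -> LinearizationModel:
    """Functional wrapper over :class:`LinearizationModel`."""
    return LinearizationModel(min_standards=min_standards).fit(standards)


def normalize_to_reflectance(image_linear: np.ndarray,
                             standard_region: np.ndarray,
                             standard_reflectance: float = 0.40) -> np.ndarray:
    """Scale each channel so the grey standard's mean equals its known
    reflectance.

    ``image_linear`` is (C, H, W) linearized responses; the returned array
    holds reflectance fractions (the standard region averages exactly
    ``standard_reflectance`` in every channel).
    """
    image_linear = np.asarray(image_linear, dtype=np.float64)
    standard_region = np.asarray(standard_region, dtype=bool)
    if not standard_region.any():
        raise CalibrationError("standard region is empty")
    out = np.empty_like(image_linear)
    for i, channel in enumerate(image_linear):
        mean = float(channel[standard_region].mean())
        if mean <= 0:
            raise CalibrationError(
                f"channel {i}: non-positive standard response {mean}")
        out[i] = channel * (standard_reflectance / mean)
    return out


def rescale_saturation(channels: np.ndarray
                       ) -> tuple[np.ndarray, float]:
    """Apply the anti-saturation storage rule.

    If the global maximum reflectance M exceeds 1, every value is divided
    by M before 16-bit quantization and the factor 1/M is recorded (e.g. a
    maximum of 120% reflectance gives a scale of 1/1.2); otherwise the
    scale is 1. Returns the stored uint16 array and the scale factor.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if not np.all(np.isfinite(channels)) or np.any(channels < 0):
        raise ValueError("channels must be finite and non-negative")
    m = float(channels.max()) if channels.size else 0.0
    scale = 1.0 / m if m > 1.0 else 1.0
    stored = np.round(channels * scale * MAX_COUNT).astype(np.uint16)
    return stored, scale


def reconstruct_reflectance(stored: np.ndarray, saturation_scale: float
                            ) -> np.ndarray:
    """Undo :func:`rescale_saturation` in floating point, restoring
    reflectances (possibly above 1; no clipping)."""
    return np.asarray(stored, dtype=np.float64) / MAX_COUNT / saturation_scale


def _scale_about_centre(image: np.ndarray, scale: float) -> np.ndarray:
    """Resample ``image`` by a uniform scale about its centre (bilinear)."""
    if scale == 1.0:
        return image
    centre = (np.asarray(image.shape) - 1) / 2.0
    # output coords -> input coords: x_in = centre + (x_out - centre)/scale
    matrix = np.eye(2) / scale
    offset = centre - matrix @ centre
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="nearest")


def _shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    return ndimage.shift(image, shift, order=1, mode="nearest")


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def align_uv_visible(vis_stack: np.ndarray, uv_stack: np.ndarray,
                     scale_bounds: tuple[float, float] = (0.95, 1.05),
                     n_scales: int = 21,
                     min_correlation: float = 0.1,
                     upsample_factor: int = 10,
                     ) -> tuple[np.ndarray, dict]:
    """Register the UV channels onto the visible channels.

    The transform is a uniform scale about the image centre plus a
    translation — the geometry change a tripod-mounted refocus induces.
    The scale is grid-searched over ``scale_bounds``; at each candidate
    scale the translation maximizing the cross-correlation between the
    visible green channel and the UV blue channel is found by phase
    correlation, and the (scale, shift) pair with the highest normalized
    cross-correlation wins.

    Returns the resampled (2, H, W) UV stack and a dict with ``scale``,
    ``shift`` (row, col) and ``correlation``.
    """
    vis_stack = np.asarray(vis_stack, dtype=np.float64)
    uv_stack = np.asarray(uv_stack, dtype=np.float64)
    ref = vis_stack[1]       # visible green
    mov = uv_stack[1]        # UV blue
    best = None
    for scale in np.linspace(scale_bounds[0], scale_bounds[1], n_scales):
        scaled = _scale_about_centre(mov, float(scale))
        shift, _, _ = phase_cross_correlation(
            ref, scaled, upsample_factor=upsample_factor, normalization=None)
        candidate = _shift(scaled, tuple(shift))
        corr = _ncc(ref, candidate)
        if best is None or corr > best[0]:
            best = (corr, float(scale), tuple(float(s) for s in shift))
    corr, scale, shift = best
    if corr < min_correlation:
        raise CalibrationError(
            f"alignment failed: best correlation {corr:.3f} below floor "
            f"{min_correlation}; supply a manual transform")
    aligned = np.stack([
        _shift(_scale_about_centre(ch, scale), shift) for ch in uv_stack])
    return aligned, {"scale": scale, "shift": shift, "correlation": corr}


def resize_to_scale(channels: np.ndarray, from_px_per_mm: float,
                    to_px_per_mm: float) -> np.ndarray:
    """Bilinear resample so the pixel pitch matches ``to_px_per_mm``.

    Used to bring controlled-condition egg photographs onto the pixel
    scale of the in-situ surround image before comparing them.
    """
    if from_px_per_mm <= 0 or to_px_per_mm <= 0:
        raise ValueError("pixel scales must be positive")
    channels = np.asarray(channels, dtype=np.float64)
    if from_px_per_mm == to_px_per_mm:
        return channels
    ratio = to_px_per_mm / from_px_per_mm
    single = channels.ndim == 2
    stack = channels[None] if single else channels
    out_shape = tuple(int(round(s * ratio)) for s in stack.shape[1:])
    resized = np.stack([
        resize(ch, out_shape, order=1, anti_aliasing=False,
               preserve_range=True) for ch in stack])
    return resized[0] if single else resized


def load_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit mask image; nonzero pixels are members."""
    from PIL import Image
    return np.asarray(Image.open(path)) != 0


def calibrate_raw(raw: RawImageSet, model: LinearizationModel,
                  align: bool = True) -> MultispectralImage:
    """Full calibration chain for one scene: linearize each channel,
    normalize against the grey standard, register UV onto visible, and
    record the saturation scale."""
    counts = np.concatenate([raw.vis_channels, raw.uv_channels], axis=0)
    linear = np.stack([model.transform(counts[i], CHANNEL_NAMES[i])
                       for i in range(5)])
    refl = normalize_to_reflectance(linear, raw.standard_region,
                                    raw.standard_reflectance)
    if align:
        uv_aligned, _ = align_uv_visible(refl[:3], refl[3:])
        refl = np.concatenate([refl[:3], uv_aligned], axis=0)
    stored, scale = rescale_saturation(refl)
    return MultispectralImage(channels=reconstruct_reflectance(stored, scale),
                              px_per_mm=raw.px_per_mm,
                              saturation_scale=scale)
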