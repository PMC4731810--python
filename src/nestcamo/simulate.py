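"""Synthetic data: reflectance spectra, calibrated nest scenes with
controllable camouflage mismatch, and nest-fate tables whose predation
hazard depends on mismatch.

The scene generator emulates the statistical structure the analysis
assumes rather than the photographs themselves: backgrounds are band-
limited 1/f^β Gaussian textures (the band gives the texture a
characteristic spatial scale so pattern mismatch is a meaningful knob)
modulating a 5-channel base reflectance, and the target is an ellipse
whose texture scale, texture amplitude, mean reflectance and colour can
each be offset from the background by a known amount. The fate generator
draws predation times from an exponential hazard that scales with a
chosen mismatch metric, with independent censoring for the non-predation
fates seen in the field (desertion, unknown fate, trampling, season end).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import MultispectralImage, RegionSet
from .colour import weber_fractions
from .survival import NestOutcome
from .vision import DEFAULT_GRID

__all__ = [
    "SceneSpec",
    "StudySpec",
    "generate_spectra",
    "generate_scene",
    "generate_study",
]

# ferret-like dichromat Weber fractions used to express the colour knob in
# JND units (UV channels ~ short receptor, visible channels ~ long receptor)
_DICHROMAT_OMEGA = weber_fractions([1.0, 14.0]).omega


def generate_spectra(n: int, grid: np.ndarray | None = None,
                     smoothness: int = 4, decay: float = 3.0,
                     seed: int = 0) -> np.ndarray:
    """Smooth positive reflectance spectra from a low-order random Fourier
    basis, clipped to (0.01, 0.99).

    ``smoothness`` is the number of harmonics and ``decay`` the exponent
    of the 1/k^decay amplitude fall-off. The steep default emulates the
    low effective dimensionality of natural reflectance spectra, whose
    variation is captured by a handful of smooth basis functions. Returns
    an (n, n_wavelengths) array on ``grid`` (default 320–680 nm).
    """
    if n < 20:
        raise ValueError("need at least 20 spectra for downstream fits")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    t = (grid - grid[0]) / (grid[-1] - grid[0])      # [0, 1]
    spectra = np.empty((n, grid.size))
    for i in range(n):
        base = rng.uniform(0.2, 0.6)
        s = np.full_like(t, base)
        for k in range(1, smoothness + 1):
            amp = rng.normal(0, 0.22 / k ** decay)
            phase = rng.uniform(0, 2 * np.pi)
            s = s + amp * np.cos(2 * np.pi * k * t + phase)
        spectra[i] = np.clip(s, 0.01, 0.99)
    return spectra


def _filter_band(white_fft: np.ndarray, beta: float,
                 period_band: tuple[float, float]) -> np.ndarray:
    """Shape a white-noise field into zero-mean unit-SD texture with power
    ∝ f^{-β}, band-limited to spatial periods in ``period_band`` px.

    Filtering a shared white field with different bands yields coherently
    related textures, so a target whose band equals the background's
    reproduces the background texture exactly.
    """
    shape = white_fft.shape
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    f = np.hypot(fy, fx)
    lo, hi = 1.0 / period_band[1], 1.0 / period_band[0]
    with np.errstate(divide="ignore"):
        amp = np.where((f >= lo) & (f <= hi), f ** (-beta / 2.0), 0.0)
    amp[0, 0] = 0.0
    tex = np.fft.ifft2(amp * white_fft).real
    sd = tex.std()
    if sd == 0:
        return tex
    return tex / sd


@dataclass
class SceneSpec:
    """Parameters of one synthetic nest scene.

    Mismatch knobs (all zero/one for a perfectly matched target):
    ``pattern_scale`` multiplies the target texture's period band;
    ``contrast_scale`` multiplies the target texture amplitude;
    ``delta_luminance`` scales the target base reflectance by (1 + Δ);
    ``delta_colour_jnd`` offsets UV against visible channels so that a
    dichromat with ferret cone ratios sees the requested JND between
    target and background base colours.
    """

    size: int = 128
    px_per_mm: float = 2.0
    base_colour: tuple = (0.35, 0.30, 0.25, 0.12, 0.10)
    beta: float = 1.0
    amplitude: float = 0.25
    period_band: tuple = (4.0, 32.0)
    target_axes: tuple | None = None     # ellipse semi-axes px
    pattern_scale: float = 1.0
    contrast_scale: float = 1.0
    delta_luminance: float = 0.0
    delta_colour_jnd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("scene size must be at least 64 px")
        if self.amplitude < 0:
            raise ValueError("texture amplitude must be non-negative")
        if not all(0 < c < 1 for c in self.base_colour):
            raise ValueError("base reflectances must lie in (0, 1)")
        if self.target_axes is None:
            self.target_axes = (self.size / 4.5, self.size / 6.0)
        if max(self.target_axes) * 2 >= self.size:
            raise ValueError("target ellipse larger than the scene")


def generate_scene(spec: SceneSpec
                   ) -> tuple[MultispectralImage, RegionSet, dict]:
    """Render a scene from its spec; returns the 5-channel reflectance
    image, the target/background masks, and the generating ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    a, b = spec.target_axes
    target = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
    # 2-px guard ring keeps boundary blending out of the background stats
    guard = ((yy - cy) / (a + 2)) ** 2 + ((xx - cx) / (b + 2)) ** 2 <= 1.0
    background = ~guard

    white_fft = np.fft.fft2(rng.normal(size=(n, n)))
    bg_tex = _filter_band(white_fft, spec.beta, spec.period_band)
    t_band = (spec.period_band[0] * spec.pattern_scale,
              spec.period_band[1] * spec.pattern_scale)
    t_tex = _filter_band(white_fft, spec.beta, t_band)

    # colour knob: opposite log offsets on UV vs visible channel groups so
    # a ferret-ratio dichromat sees exactly delta_colour_jnd
    h = spec.delta_colour_jnd * np.hypot(*_DICHROMAT_OMEGA) / 2.0
    colour_gain = np.array([np.exp(-h)] * 3 + [np.exp(h)] * 2)

    base = np.asarray(spec.base_colour, dtype=float)
    t_base = base * (1.0 + spec.delta_luminance) * colour_gain
    t_amp = spec.amplitude * spec.contrast_scale

    channels = np.empty((5, n, n))
    for c in range(5):
        bg_field = base[c] * (1.0 + spec.amplitude * bg_tex)
        t_field = t_base[c] * (1.0 + t_amp * t_tex)
        channels[c] = np.where(target, t_field, bg_field)
    channels = np.clip(channels, 1e-3, None)

    image = MultispectralImage(channels=channels, px_per_mm=spec.px_per_mm)
    regions = RegionSet(target_mask=target, background_mask=background)
    truth = {
        "pattern_scale": spec.pattern_scale,
        "contrast_scale": spec.contrast_scale,
        "delta_luminance": spec.delta_luminance,
        "delta_colour_jnd": spec.delta_colour_jnd,
        "period_band": spec.period_band,
        "target_period_band": t_band,
        "amplitude": spec.amplitude,
        "seed": spec.seed,
    }
    return image, regions, truth


@dataclass
class StudySpec:
    """Design of a synthetic nest-survival study.

    Defaults emulate a dry-season ground-nester study: about a month of
    incubation, a baseline predation hazard giving roughly a one-third
    predation rate over incubation, and independent censoring for the
    non-predation fates (desertion dominating).
    """

    n_nests: int = 79
    incubation_days: float = 28.0
    baseline_hazard: float = 0.015       # per day
    effect_size: float = 1.0             # log-hazard per SD of mismatch
    censoring_rates: dict = field(default_factory=lambda: {
        "desertion": 0.20, "unknown_fate": 0.09,
        "trampling": 0.025, "season_end": 0.02})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nests < 1:
            raise ValueError("need at least one nest")
        rates = list(self.censoring_rates.values())
        if any(r < 0 or r > 1 for r in rates) or sum(rates) >= 1:
            raise ValueError("censoring rates must lie in [0,1] and sum < 1")


def generate_study(spec: StudySpec, mismatch) -> list[NestOutcome]:
    """Draw nest fates whose predation hazard depends on mismatch.

    Predation times are exponential with rate λ·exp(β·z) where z is the
    standardized mismatch value; each nest may independently be censored
    by one of the configured reasons at a uniform time within incubation;
    the observed time is the earliest of predation, censoring and hatch.
    """
    mismatch = np.asarray(mismatch, dtype=float)
    if mismatch.size != spec.n_nests:
        raise ValueError("one mismatch value per nest required")
    if not np.all(np.isfinite(mismatch)):
        raise ValueError("mismatch values must be finite")
    sd = mismatch.std()
    z = (mismatch - mismatch.mean()) / sd if sd > 0 else np.zeros_like(mismatch)
    rng = np.random.default_rng(spec.seed)
    reasons = list(spec.censoring_rates)
    probs = np.array([spec.censoring_rates[r] for r in reasons])
    probs = np.concatenate([probs, [1.0 - probs.sum()]])

    outcomes = []
    for i in range(spec.n_nests):
        rate = spec.baseline_hazard * np.exp(spec.effect_size * z[i])
        t_pred = rng.exponential(1.0 / rate)
        which = rng.choice(len(reasons) + 1, p=probs)
        t_cens = (rng.uniform(0.5, spec.incubation_days)
                  if which < len(reasons) else np.inf)
        t_obs = min(t_pred, t_cens, spec.incubation_days)
        if t_pred <= min(t_cens, spec.incubation_days):
            event, reason = 1, "depredated"
        elif t_cens <= spec.incubation_days:
            event, reason = 0, reasons[which]
        else:
            event, reason = 0, "hatched"
        outcomes.append(NestOutcome(
            nest_id=f"nest_{i:03d}", species="synthetic",
            time_days=max(t_obs, 1e-6), event=event, censor_reason=reason))
    return outcomes
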