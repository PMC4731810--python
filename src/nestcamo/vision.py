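"""Predator vision modelling: quantum catches and the polynomial mapping
from camera channels to receptor cone-catch images.

A camera, however carefully calibrated, does not share a predator's
spectral sensitivities. The standard workaround is empirical: compute, for
a large library of natural reflectance spectra, both the camera's responses
and the predator's receptor quantum catches, then regress receptor catches
on camera responses with a low-order polynomial. Applying the fitted
polynomial per pixel converts a five-channel reflectance image into a
cone-catch image for that visual system. Three model systems are built in:
ferret (dichromat), human (trichromat) and common peafowl (tetrachromat,
plus a double-cone channel carrying avian luminance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.preprocessing import PolynomialFeatures

__all__ = [
    "SensitivityCurve",
    "VisualSystem",
    "quantum_catch",
    "gaussian_sensitivity",
    "camera_sensitivities",
    "builtin_visual_system",
    "ConeCatchMapper",
    "ConeCatchImage",
]

DEFAULT_GRID = np.arange(320.0, 681.0, 4.0)


@dataclass
class SensitivityCurve:
    """A spectral curve (sensitivity or illuminant) on an ascending
    wavelength grid in nm."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelength grid and values differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if np.any(self.values < 0) or not self.values.any():
            raise ValueError("sensitivities must be non-negative, not all zero")

    @classmethod
    def from_csv(cls, path: str | Path, value_column: str = "value"
                 ) -> "SensitivityCurve":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df[value_column].to_numpy())


def gaussian_sensitivity(centre_nm: float, width_nm: float,
                         grid: np.ndarray | None = None) -> SensitivityCurve:
    """Synthetic Gaussian receptor/camera sensitivity (peak 1)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    values = np.exp(-0.5 * ((grid - centre_nm) / width_nm) ** 2)
    return SensitivityCurve(grid, values)


def flat_illuminant(grid: np.ndarray | None = None) -> SensitivityCurve:
    """Equal-energy illuminant (the default; configurable everywhere)."""
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    return SensitivityCurve(grid, np.ones_like(grid))


def camera_sensitivities(grid: np.ndarray | None = None
                         ) -> dict[str, SensitivityCurve]:
    """Synthetic Gaussian curves for the five camera channels: visible
    R/G/B plus the red and blue channels behind the UV-pass filter."""
    return {
        "vis_r": gaussian_sensitivity(600, 40, grid),
        "vis_g": gaussian_sensitivity(535, 40, grid),
        "vis_b": gaussian_sensitivity(460, 35, grid),
        "uv_r": gaussian_sensitivity(368, 18, grid),
        "uv_b": gaussian_sensitivity(345, 16, grid),
    }


@dataclass
class VisualSystem:
    """A predator visual system: chromatic receptors ordered shortest to
    longest wavelength, their relative abundances (cone ratios), and the
    rule defining the luminance channel.

    ``luminance_rule`` is either a receptor name (single channel, e.g. the
    ferret L cone or the avian double cone) or a list of names whose
    pixelwise mean is luminance (human: ``["m", "l"]`` for (L+M)/2).
    Receptors named in the rule but absent from ``receptors`` (the avian
    double cone) are carried as an extra achromatic channel: they get a
    fitted mapping but take no part in colour discrimination.
    """

    name: str
    receptors: list[str]
    cone_ratio: dict[str, float]
    luminance_rule: str | list[str]
    sensitivities: dict[str, SensitivityCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.receptors) < 2:
            raise ValueError("a visual system needs at least 2 receptors")
        for r in self.receptors:
            if self.cone_ratio.get(r, 0) <= 0:
                raise ValueError(f"receptor {r!r} needs a positive cone ratio")
        for r in self.luminance_channels:
            if r not in self.all_channels:
                raise ValueError(f"luminance rule names unknown receptor {r!r}")

    @property
    def luminance_channels(self) -> list[str]:
        rule = self.luminance_rule
        return [rule] if isinstance(rule, str) else list(rule)

    @property
    def all_channels(self) -> list[str]:
        """Chromatic receptors plus any achromatic-only channel."""
        extra = [r for r in self.luminance_channels if r not in self.receptors]
        return list(self.receptors) + extra

    @property
    def n_receptors(self) -> int:
        return len(self.receptors)


def builtin_visual_system(name: str, grid: np.ndarray | None = None
                          ) -> VisualSystem:
    """Ferret, human or peafowl with synthetic Gaussian sensitivities.

    Cone ratios (shortest to longest wavelength): ferret 1:14,
    human 1:5.49:10.99, peafowl 1:1.9:2.2:2.1. Luminance: ferret L cone,
    human (L+M)/2, peafowl double cone.
    """
    if name == "ferret":
        return VisualSystem(
            name="ferret", receptors=["s", "l"],
            cone_ratio={"s": 1.0, "l": 14.0},
            luminance_rule="l",
            sensitivities={"s": gaussian_sensitivity(430, 35, grid),
                           "l": gaussian_sensitivity(558, 50, grid)})
    if name == "human":
        return VisualSystem(
            name="human", receptors=["s", "m", "l"],
            cone_ratio={"s": 1.0, "m": 5.49, "l": 10.99},
            luminance_rule=["m", "l"],
            sensitivities={"s": gaussian_sensitivity(442, 30, grid),
                           "m": gaussian_sensitivity(543, 45, grid),
                           "l": gaussian_sensitivity(570, 50, grid)})
    if name == "peafowl":
        return VisualSystem(
            name="peafowl", receptors=["u", "s", "m", "l"],
            cone_ratio={"u": 1.0, "s": 1.9, "m": 2.2, "l": 2.1},
            luminance_rule="dbl",
            sensitivities={"u": gaussian_sensitivity(370, 25, grid),
                           "s": gaussian_sensitivity(450, 30, grid),
                           "m": gaussian_sensitivity(505, 35, grid),
                           "l": gaussian_sensitivity(565, 45, grid),
                           "dbl": gaussian_sensitivity(560, 80, grid)})
    raise ValueError(f"unknown visual system {name!r}")


def quantum_catch(reflectance: np.ndarray, sensitivity: SensitivityCurve,
                  illuminant: SensitivityCurve | None = None) -> float:
    """Receptor quantum catch of a surface, normalized so a perfect
    reflector gives 1.

    catch = ∫ R(λ) S(λ) I(λ) dλ / ∫ S(λ) I(λ) dλ  (trapezoidal rule).
    """
    if illuminant is None:
        illuminant = flat_illuminant(sensitivity.wavelengths)
    if (sensitivity.wavelengths.shape != illuminant.wavelengths.shape
            or not np.allclose(sensitivity.wavelengths, illuminant.wavelengths)):
        raise ValueError("sensitivity and illuminant wavelength grids differ")
    reflectance = np.asarray(reflectance, dtype=float)
    if reflectance.shape != sensitivity.wavelengths.shape:
        raise ValueError("reflectance not on the sensitivity grid")
    w = sensitivity.wavelengths
    si = sensitivity.values * illuminant.values
    return float(np.trapezoid(reflectance * si, w) / np.trapezoid(si, w))


@dataclass
class ConeCatchImage:
    """Per-receptor quantal-catch channels for one visual system."""

    channels: dict[str, np.ndarray]
    system: VisualSystem
    px_per_mm: float = 1.0

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("cone-catch channels not congruent")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def receptor_stack(self) -> np.ndarray:
        """(n_receptors, H, W) stack of the chromatic channels in
        shortest-to-longest order."""
        return np.stack([self.channels[r] for r in self.system.receptors])


class ConeCatchMapper:
    """Polynomial camera-to-cone-catch mapping, one regression per receptor,
    in the fit/transform idiom.

    ``fit`` takes a spectral library; for each spectrum the five camera
    quantum catches form the regressors and each receptor's quantum catch
    the response, fitted with a degree-``degree`` polynomial (interactions
    included, intercept on). ``transform`` evaluates the polynomials
    per pixel of a five-channel reflectance image.

    Parameters
    ----------
    system : VisualSystem
        Receptors (including any achromatic-only channel) to map to.
    degree : int, default 2
        Polynomial degree over the 5 camera catches.
    clamp_floor : float, default 1e-6
        Negative predicted catches (polynomial extrapolation) are clamped
        here; downstream log-ratio colour distances need positive catches.

    Attributes
    ----------
    coef_ : dict receptor -> fitted LinearRegression
    r_squared_ : dict receptor -> training R²
    """

    def __init__(self, system: VisualSystem, degree: int = 2,
                 clamp_floor: float = 1e-6):
        self.system = system
        self.degree = degree
        self.clamp_floor = clamp_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"system": self.system, "degree": self.degree,
                "clamp_floor": self.clamp_floor}

    def set_params(self, **params) -> "ConeCatchMapper":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, library: np.ndarray, grid: np.ndarray,
            camera: dict[str, SensitivityCurve] | None = None,
            illuminant: SensitivityCurve | None = None) -> "ConeCatchMapper":
        """Fit the per-receptor polynomials on a reflectance library.

        Parameters
        ----------
        library : (n_spectra, n_wavelengths) reflectance spectra
        grid : shared wavelength grid in nm
        camera : camera channel sensitivities (synthetic Gaussians if None)
        illuminant : defaults to equal-energy
        """
        library = np.asarray(library, dtype=float)
        grid = np.asarray(grid, dtype=float)
        if camera is None:
            camera = camera_sensitivities(grid)
        if illuminant is None:
            illuminant = flat_illuminant(grid)
        cam_names = list(camera)
        X = np.array([[quantum_catch(spec, camera[c], illuminant)
                       for c in cam_names] for spec in library])
        self._poly = PolynomialFeatures(degree=self.degree,
                                        include_bias=False)
        Xp = self._poly.fit_transform(X)
        if Xp.shape[0] <= Xp.shape[1]:
            raise ValueError(
                f"library of {Xp.shape[0]} spectra too small for a basis of "
                f"{Xp.shape[1]} terms")
        self.camera_names_ = cam_names
        self.coef_ = {}
        self.r_squared_ = {}
        for receptor in self.system.all_channels:
            sens = self.system.sensitivities[receptor]
            y = np.array([quantum_catch(spec, sens, illuminant)
                          for spec in library])
            reg = LinearRegression().fit(Xp, y)
            self.coef_[receptor] = reg
            self.r_squared_[receptor] = float(reg.score(Xp, y))
        return self

    def predict(self, camera_catches: np.ndarray) -> dict[str, np.ndarray]:
        """Receptor catches for (n, 5) camera catch vectors."""
        Xp = self._poly.transform(np.asarray(camera_catches, dtype=float))
        return {r: np.clip(reg.predict(Xp), self.clamp_floor, None)
                for r, reg in self.coef_.items()}

    def transform(self, image) -> ConeCatchImage:
        """Map a five-channel reflectance image to a cone-catch image.

        Accepts a :class:`~nestcamo.calibration.MultispectralImage` or a
        raw (5, H, W) array. Calibrated reflectance channels serve directly
        as the camera quantum catches.
        """
        channels = getattr(image, "channels", image)
        channels = np.asarray(channels, dtype=float)
        if channels.ndim != 3 or channels.shape[0] != 5:
            raise ValueError("expected a (5, H, W) reflectance stack")
        h, w = channels.shape[1:]
        flat = channels.reshape(5, -1).T
        preds = self.predict(flat)
        out = {r: v.reshape(h, w) for r, v in preds.items()}
        return ConeCatchImage(channels=out, system=self.system,
                              px_per_mm=getattr(image, "px_per_mm", 1.0))

    def to_json(self, path: str | Path) -> None:
        """Persist basis description, coefficients and training R²."""
        payload = {
            "system": self.system.name,
            "degree": self.degree,
            "camera_names": self.camera_names_,
            "feature_names": list(
                self._poly.get_feature_names_out(self.camera_names_)),
            "receptors": {
                r: {"coef": reg.coef_.tolist(),
                    "intercept": float(reg.intercept_),
                    "r_squared": self.r_squared_[r]}
                for r, reg in self.coef_.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def fit_cone_catch_mapping(library, grid, system, camera=None,
                           illuminant=None, degree: int = 2
                           ) -> ConeCatchMapper:
    """Functional wrapper over :class:`ConeCatchMapper`."""
    return ConeCatchMapper(system, degree=degree).fit(
        library, grid, camera=camera, illuminant=illuminant)


def apply_mapping(image, mapping: ConeCatchMapper) -> ConeCatchImage:
    """Functional wrapper over :meth:`ConeCatchMapper.transform`."""
    return mapping.transform(image)
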