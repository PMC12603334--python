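"""Light-source beam profiles and the photodiode detector model.

Emission directions are drawn by inverse-transform sampling from a tabulated
angular intensity I(theta).  For a rotationally symmetric emitter radiating
into 3-D, the polar density includes the solid-angle weight,
p(theta) proportional to I(theta) * sin(theta); a planar-density mode
(p proportional to I alone) is available for comparison with frameworks
that tabulate I(theta) as a per-angle density.

The detector is a square aperture on the skin surface with a tabulated
angular sensitivity over the exit polar angle (cosine response by default)
and a per-wavelength spectral factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

from .skin_model import ConfigurationError, ValidationError

__all__ = [
    "BeamProfile",
    "SourceConfig",
    "DetectorModel",
    "normalize_and_cdf",
    "load_beam_profile",
    "sample_emission",
    "tilt_direction",
    "detector_response",
    "default_detector",
]

PROFILE_IDS = ("LED_R", "VCSEL_R", "LED_IR", "VCSEL_IR")
TILTS = (-45.0, 0.0, 45.0)


@dataclass(frozen=True)
class BeamProfile:
    """Tabulated angular emission density with its CDF lookup table."""

    profile_id: str
    theta: np.ndarray  # radians, strictly increasing, starting at 0
    intensity: np.ndarray  # relative intensity I(theta), >= 0
    density: np.ndarray  # normalized p(theta) [1/rad]
    cdf: np.ndarray  # F(theta), F[0]=0, F[-1]=1

    def __post_init__(self):
        if not np.isclose(self.cdf[-1], 1.0, atol=1e-9):
            raise ValidationError("beam-profile CDF must end at 1")
        if np.any(np.diff(self.cdf) < -1e-12):
            raise ValidationError("beam-profile CDF must be nondecreasing")


def normalize_and_cdf(
    theta_grid: np.ndarray,
    relative_intensity: np.ndarray,
    *,
    profile_id: str = "custom",
    solid_angle: bool = True,
) -> BeamProfile:
    """Build a :class:`BeamProfile` from a tabulated I(theta).

    ``theta_grid`` is in radians and must be strictly increasing; the CDF is
    accumulated with the trapezoid rule.  With ``solid_angle=True`` (default)
    the polar density is I(theta)*sin(theta), the physically consistent
    weighting for rotationally symmetric emission into 3-D.
    """
    theta = np.asarray(theta_grid, dtype=float)
    inten = np.asarray(relative_intensity, dtype=float)
    if theta.ndim != 1 or theta.shape != inten.shape:
        raise ValidationError("theta grid and intensity must be 1-D and equal length")
    if np.any(np.diff(theta) <= 0):
        raise ValidationError("theta grid must be strictly increasing")
    if np.any(inten < 0):
        raise ValidationError("intensity must be >= 0")
    weight = inten * np.sin(theta) if solid_angle else inten.copy()
    segments = 0.5 * (weight[1:] + weight[:-1]) * np.diff(theta)
    total = segments.sum()
    if total <= 0:
        raise ValidationError("intensity is identically zero")
    cdf = np.concatenate([[0.0], np.cumsum(segments)]) / total
    cdf = np.maximum.accumulate(np.clip(cdf, 0.0, 1.0))
    cdf[-1] = 1.0
    return BeamProfile(
        profile_id=profile_id,
        theta=theta,
        intensity=inten,
        density=weight / total,
        cdf=cdf,
    )


def _bundled_frame(name: str) -> pd.DataFrame:
    text = resources.files("oximc.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), comment="#")


def load_beam_profile(profile_id: str, *, solid_angle: bool = True) -> BeamProfile:
    """Load one of the bundled profiles (LED_R, VCSEL_R, LED_IR, VCSEL_IR)."""
    df = _bundled_frame("beam_profiles.csv")
    sub = df[df["profile_id"] == profile_id]
    if sub.empty:
        raise ConfigurationError(
            f"unknown beam profile {profile_id!r}; available: {PROFILE_IDS}"
        )
    return normalize_and_cdf(
        np.radians(sub["theta_deg"].to_numpy(float)),
        sub["relative_intensity"].to_numpy(float),
        profile_id=profile_id,
        solid_angle=solid_angle,
    )


@dataclass(frozen=True)
class SourceConfig:
    """Source placement: which profile, at which wavelength, with which tilt.

    The tilt rotates the beam about the horizontal axis perpendicular to the
    source-detector axis; +45 deg tips the beam centroid toward the detector,
    -45 deg away from it.  LED profiles are only used untilted.
    """

    profile_id: str
    wavelength: float
    tilt_deg: float = 0.0
    position: tuple[float, float] = (0.0, 0.0)  # on the z = 0 plane [mm]
    custom_profile: BeamProfile | None = None  # overrides the bundled table

    def __post_init__(self):
        if self.custom_profile is None and self.profile_id not in PROFILE_IDS:
            raise ConfigurationError(f"unknown profile_id {self.profile_id!r}")
        if self.tilt_deg not in TILTS:
            raise ValidationError(f"tilt must be one of {TILTS}")
        if self.profile_id.startswith("LED") and self.tilt_deg != 0.0:
            raise ValidationError("LED profiles are only simulated untilted (0 deg)")

    def profile(self) -> BeamProfile:
        if self.custom_profile is not None:
            return self.custom_profile
        return load_beam_profile(self.profile_id)


def sample_theta(profile: BeamProfile, u: np.ndarray) -> np.ndarray:
    """Invert the tabulated CDF by linear interpolation: theta = F^-1(u)."""
    return np.interp(u, profile.cdf, profile.theta)


def sample_emission(profile: BeamProfile, rng: np.random.Generator) -> np.ndarray:
    """Draw one emission direction (unit vector, +z into tissue)."""
    theta = float(sample_theta(profile, rng.random()))
    phi = 2.0 * math.pi * rng.random()
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def tilt_direction(
    direction: np.ndarray,
    tilt_deg: float,
    source_detector_axis: np.ndarray = np.array([1.0, 0.0, 0.0]),
) -> np.ndarray:
    """Rotate ``direction`` by the beam tilt.

    The rotation axis is horizontal and perpendicular to the source-detector
    axis, so a +tilt tips the beam centroid toward the detector.  Norm is
    preserved exactly.
    """
    if abs(tilt_deg) >= 90.0:
        raise ValidationError("|tilt| must be < 90 deg for the beam to enter tissue")
    d = np.asarray(direction, dtype=float)
    a = np.asarray(source_detector_axis, dtype=float)
    a = a / np.linalg.norm(a)
    t = math.radians(tilt_deg)
    ct, st = math.cos(t), math.sin(t)
    z = np.array([0.0, 0.0, 1.0])
    # Rodrigues rotation about axis k = z x a (horizontal, perpendicular to a);
    # with a = +x this maps (0,0,1) to (sin t, 0, cos t).
    k = np.cross(z, a)
    k = k / np.linalg.norm(k)
    return d * ct + np.cross(k, d) * st + k * np.dot(k, d) * (1.0 - ct)


@dataclass(frozen=True)
class DetectorModel:
    """Square-aperture photodiode on the skin surface.

    ``center`` is the aperture center on z = 0 (source-detector distance is
    center-to-center); ``half_width`` is half the side length.  Angular
    sensitivity is tabulated over the exit polar angle in air and applied
    multiplicatively together with the per-wavelength spectral factor.
    """

    center: tuple[float, float] = (4.0, 0.0)
    half_width: float = 0.5  # [mm]; 1 mm square aperture
    angle_deg: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 91.0, 5.0)
    )
    angular_sensitivity: np.ndarray = field(
        default_factory=lambda: np.cos(np.radians(np.arange(0.0, 91.0, 5.0)))
    )
    spectral_sensitivity: dict | None = None  # wavelength -> factor; None = 1.0

    def __post_init__(self):
        if not self.half_width > 0:
            raise ValidationError("detector aperture must have positive area")
        s = np.asarray(self.angular_sensitivity)
        if np.any(s < 0) or np.any(s > 1):
            raise ValidationError("angular sensitivity must be in [0, 1]")

    def spectral_factor(self, wavelength: float) -> float:
        if self.spectral_sensitivity is None:
            return 1.0
        if wavelength not in self.spectral_sensitivity:
            raise ConfigurationError(f"no spectral factor for {wavelength} nm")
        return float(self.spectral_sensitivity[wavelength])


def default_detector(sdd_mm: float) -> DetectorModel:
    """Detector from the bundled sensitivity tables at the given distance."""
    ang = _bundled_frame("detector_angular.csv")
    spec = _bundled_frame("detector_spectral.csv")
    return DetectorModel(
        center=(float(sdd_mm), 0.0),
        half_width=0.5,
        angle_deg=ang["angle_deg"].to_numpy(float),
        angular_sensitivity=ang["sensitivity"].to_numpy(float),
        spectral_sensitivity=dict(zip(spec["wavelength"], spec["factor"])),
    )


def detector_response(
    exit_position: np.ndarray,
    exit_direction: np.ndarray,
    wavelength: float,
    det: DetectorModel,
) -> float | None:
    """Acceptance weight factor for a photon leaving the tissue surface.

    Returns ``None`` if the exit point misses the aperture, otherwise the
    product of the angular sensitivity at the exit polar angle (in air) and
    the spectral factor.  The factor never exceeds 1.
    """
    x, y = float(exit_position[0]), float(exit_position[1])
    cx, cy = det.center
    if abs(x - cx) > det.half_width or abs(y - cy) > det.half_width:
        return None
    cos_exit = abs(float(exit_direction[2]))
    angle = math.degrees(math.acos(min(1.0, cos_exit)))
    ang_sens = float(np.interp(angle, det.angle_deg, det.angular_sensitivity))
    return ang_sens * det.spectral_factor(wavelength)
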