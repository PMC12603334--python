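"""Weighted photon-packet transport through the layered tissue stack.

The module exposes the individual transport primitives (specular entry,
exponential step sampling, boundary Fresnel decisions, Henyey-Greenstein
scattering, albedo weight update, Russian roulette) as plain functions, and
two run drivers built on the compiled kernel:

``run_photon_simulation``
    one condition (one tissue stack), one weight channel;
``run_paired_simulation``
    several physiological conditions that share scattering, anisotropy and
    refractive indices (systole/diastole, melanin or saturation levels) as
    weight channels of a single transport pass — exact common-path pairing,
    so intensity differences between conditions are driven purely by the
    absorption contrast, not by sampling noise.

Two step-length modes exist.  "mcml-standard" samples the step from the
total attenuation mu_t = mu_a + mu_s and applies the albedo weight update —
the classic unbiased estimator.  "paper-literal" samples the step from
mu_s alone with the same weight update; for tissue (mu_a << mu_s) the two
agree closely, and only the literal mode admits shared-path channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._kernels import _fresnel, _hg_cos, transport
from .beam_sources import BeamProfile, DetectorModel, SourceConfig
from .skin_model import TissueStack, ValidationError

__all__ = [
    "TransportParams",
    "DetectionTally",
    "RunResult",
    "specular_entry",
    "sample_step",
    "fresnel_boundary",
    "hg_scatter",
    "absorb",
    "roulette",
    "run_photon_simulation",
    "run_paired_simulation",
    "epidermis_absorption_fraction",
]

MCML_STANDARD = "mcml-standard"
PAPER_LITERAL = "paper-literal"


@dataclass(frozen=True)
class TransportParams:
    """Numerical knobs of the transport loop.

    step_mode: "mcml-standard" (default) or "paper-literal"; see module note.
    normalization: "throughput" reports I = sum(w_d)/N_launched (proportional
    to detected flux); "eq7-literal" reports the mean detected weight
    sum(w_d)/N_d.
    """

    step_mode: str = MCML_STANDARD
    normalization: str = "throughput"
    roulette_threshold: float = 1e-4
    roulette_survival: float = 10.0
    r_max_mm: float = 30.0
    z_max_mm: float = 30.0
    max_events: int = 1_000_000

    def __post_init__(self):
        if self.step_mode not in (MCML_STANDARD, PAPER_LITERAL):
            raise ValidationError(f"unknown step_mode {self.step_mode!r}")
        if self.normalization not in ("throughput", "eq7-literal"):
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if not (self.roulette_threshold > 0 and self.roulette_survival > 1):
            raise ValidationError("invalid roulette parameters")


@dataclass(frozen=True)
class DetectionTally:
    """Weight bookkeeping of one run (one weight channel).

    ``escaped_weight`` includes the detected weight; ``residual_weight`` is
    the signed balance of roulette kills/boosts plus cutoff and event-limit
    terminations, so that specular + absorbed + escaped + residual equals
    the launched weight exactly.
    """

    n_launched: int
    n_rejected: int
    n_detected: int
    specular_weight: float
    absorbed_by_layer: np.ndarray
    absorbed_detected_by_layer: np.ndarray
    escaped_weight: float
    detected_weight: float
    residual_weight: float
    unscattered_terminal_weight: float
    layer_names: tuple[str, ...]

    @property
    def sum_w_d(self) -> float:
        return self.detected_weight

    @property
    def i_star_throughput(self) -> float:
        return self.detected_weight / self.n_launched

    @property
    def i_star_mean(self) -> float:
        """Mean detected weight (literal reading of the intensity estimator)."""
        if self.n_detected == 0:
            return 0.0
        return self.detected_weight / self.n_detected

    def audit_error(self) -> float:
        """Relative weight-conservation defect; ~1e-16, never above 1e-6."""
        total = (
            self.specular_weight
            + float(self.absorbed_by_layer.sum())
            + self.escaped_weight
            + self.residual_weight
        )
        return abs(total - self.n_launched) / self.n_launched


@dataclass(frozen=True)
class RunResult:
    """One transport run: configuration echo plus its detection tally."""

    source: SourceConfig
    sdd_mm: float
    stack: TissueStack
    seed: int
    n_packets: int
    params: TransportParams
    tally: DetectionTally

    @property
    def intensity(self) -> float:
        if self.params.normalization == "eq7-literal":
            return self.tally.i_star_mean
        return self.tally.i_star_throughput


# ---------------------------------------------------------------------------
# transport primitives (thin wrappers over the compiled helpers)
# ---------------------------------------------------------------------------

def specular_entry(
    direction: np.ndarray, n_air: float, n_surface: float
) -> tuple[float, float, np.ndarray]:
    """Specular reflection and refraction at tissue entry.

    Returns (R_spec, initial weight 1 - R_spec, refracted unit direction).
    The incidence angle is taken from the actual direction; grazing
    incidence (no downward component) raises: such packets never enter.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if d[2] <= 0:
        raise ValidationError("direction must point into tissue (positive z)")
    r_spec, cos_t = _fresnel(d[2], n_air, n_surface)
    scale = n_air / n_surface
    refracted = np.array([d[0] * scale, d[1] * scale, cos_t])
    return float(r_spec), 1.0 - float(r_spec), refracted


def sample_step(mu: float, rng: np.random.Generator) -> float:
    """Exponential free-path sample l = -ln(xi)/mu [mm]."""
    if not mu > 0:
        raise ValidationError("attenuation coefficient must be > 0")
    xi = 1.0 - rng.random()  # uniform on (0, 1]
    return -math.log(xi) / mu


def fresnel_boundary(
    theta_i: float, n_i: float, n_t: float, rng: np.random.Generator
) -> tuple[bool, float]:
    """Stochastic transmit/reflect decision at a refractive-index boundary.

    Returns (transmitted, theta_out): the refraction angle when transmitted,
    the mirrored incidence angle otherwise.  The packet is transmitted when
    the reflectance R is smaller than a uniform random number.
    """
    if not (0 <= theta_i < math.pi / 2):
        raise ValidationError("incidence angle must be in [0, pi/2)")
    r, cos_t = _fresnel(math.cos(theta_i), n_i, n_t)
    if rng.random() > r:
        return True, math.acos(cos_t)
    return False, theta_i


def hg_scatter(g: float, rng: np.random.Generator) -> tuple[float, float]:
    """Sample a Henyey-Greenstein deflection (theta, phi)."""
    if not (0 <= g < 1):
        raise ValidationError("anisotropy g must be in [0, 1)")
    cos_t = _hg_cos(g, rng.random())
    return math.acos(cos_t), 2.0 * math.pi * rng.random()


def absorb(w: float, mu_a: float, mu_s: float) -> tuple[float, float]:
    """Albedo weight update: returns (new weight, absorbed increment)."""
    if mu_a < 0 or not mu_s > 0:
        raise ValidationError("require mu_a >= 0 and mu_s > 0")
    dw = w * mu_a / (mu_s + mu_a)
    return w - dw, dw


def roulette(
    w: float, threshold: float, survival_factor: float, rng: np.random.Generator
) -> float:
    """Unbiased termination of low-weight packets; returns the new weight."""
    if not (threshold > 0 and survival_factor > 1):
        raise ValidationError("invalid roulette parameters")
    if w >= threshold:
        return w
    if rng.random() < 1.0 / survival_factor:
        return w * survival_factor
    return 0.0


# ---------------------------------------------------------------------------
# run drivers
# ---------------------------------------------------------------------------

def _check_shared_geometry(stacks) -> None:
    ref = stacks[0]
    _, mu_s0, g0, n0 = ref.arrays()
    b0 = ref.boundaries
    for s in stacks[1:]:
        _, mu_s, g, n = s.arrays()
        if (
            not np.array_equal(mu_s, mu_s0)
            or not np.array_equal(g, g0)
            or not np.array_equal(n, n0)
            or not np.array_equal(s.boundaries, b0)
        ):
            raise ValidationError(
                "paired channels must share mu_s, g, n and geometry "
                "(they may differ only in absorption)"
            )


def _run_kernel(
    source: SourceConfig,
    detector: DetectorModel,
    stacks,
    n_packets: int,
    seed: int,
    params: TransportParams,
):
    profile = source.profile()
    mu_a_cols = []
    for s in stacks:
        mu_a, _, _, _ = s.arrays()
        mu_a_cols.append(mu_a)
    _, mu_s, g, n = stacks[0].arrays()
    zb = stacks[0].boundaries.copy()
    zb[-1] = 1e30  # semi-infinite terminal layer
    mu_a_mat = np.column_stack(mu_a_cols)

    return transport(
        seed,
        n_packets,
        zb,
        mu_a_mat,
        mu_s,
        g,
        n,
        1.0,  # refractive index of air
        profile.theta,
        profile.cdf,
        math.radians(source.tilt_deg),
        float(detector.center[0]),
        float(detector.half_width),
        np.radians(np.asarray(detector.angle_deg, dtype=float)),
        np.asarray(detector.angular_sensitivity, dtype=float),
        detector.spectral_factor(source.wavelength),
        params.step_mode == MCML_STANDARD,
        params.roulette_threshold,
        params.roulette_survival,
        params.r_max_mm,
        params.z_max_mm,
        params.max_events,
    )


def _tally_from_kernel(out, k: int, n_packets: int, names) -> DetectionTally:
    (spec, n_rej, n_det, absorbed, absorbed_det, escaped, det_w, resid, unsc) = out
    return DetectionTally(
        n_launched=n_packets,
        n_rejected=int(n_rej),
        n_detected=int(n_det),
        specular_weight=float(spec),
        absorbed_by_layer=absorbed[:, k].copy(),
        absorbed_detected_by_layer=absorbed_det[:, k].copy(),
        escaped_weight=float(escaped[k]),
        detected_weight=float(det_w[k]),
        residual_weight=float(resid[k]),
        unscattered_terminal_weight=float(unsc),
        layer_names=tuple(names),
    )


def run_photon_simulation(
    source: SourceConfig,
    detector: DetectorModel,
    stack: TissueStack,
    n_packets: int,
    seed: int,
    params: TransportParams | None = None,
) -> RunResult:
    """Transport ``n_packets`` photon packets through one tissue stack.

    Deterministic: identical (source, detector, stack, n_packets, seed,
    params) reproduce the tally bit for bit.
    """
    if n_packets < 1:
        raise ValidationError("n_packets must be >= 1")
    params = params or TransportParams()
    out = _run_kernel(source, detector, [stack], n_packets, seed, params)
    tally = _tally_from_kernel(out, 0, n_packets, stack.names)
    return RunResult(
        source=source,
        sdd_mm=float(detector.center[0]),
        stack=stack,
        seed=seed,
        n_packets=n_packets,
        params=params,
        tally=tally,
    )


def run_paired_simulation(
    source: SourceConfig,
    detector: DetectorModel,
    stacks,
    n_packets: int,
    seed: int,
    params: TransportParams | None = None,
) -> list[RunResult]:
    """Transport several absorption conditions with common random numbers.

    In "paper-literal" mode all conditions ride the same photon paths as
    weight channels of one kernel pass (exact pairing).  In "mcml-standard"
    mode each condition is an independent run launched from the same seed,
    so the random streams — though not the paths — are shared.
    """
    if n_packets < 1:
        raise ValidationError("n_packets must be >= 1")
    params = params or TransportParams()
    stacks = list(stacks)
    _check_shared_geometry(stacks)

    if params.step_mode == PAPER_LITERAL:
        out = _run_kernel(source, detector, stacks, n_packets, seed, params)
        results = []
        for k, s in enumerate(stacks):
            tally = _tally_from_kernel(out, k, n_packets, s.names)
            results.append(
                RunResult(source, float(detector.center[0]), s, seed,
                          n_packets, params, tally)
            )
        return results
    return [
        run_photon_simulation(source, detector, s, n_packets, seed, params)
        for s in stacks
    ]


def epidermis_absorption_fraction(tally: DetectionTally) -> float:
    """Epidermal share of the absorption along detected photons' paths."""
    if tally.n_detected == 0:
        raise ValidationError("no detected photons: absorption fraction undefined")
    total = float(tally.absorbed_detected_by_layer.sum())
    if total == 0.0:
        return 0.0
    epi = tally.layer_names.index("epidermis")
    return float(tally.absorbed_detected_by_layer[epi]) / total
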