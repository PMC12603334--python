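"""Engine-independent analytic oracles for certifying the transport core.

Everything here is computed in closed form or by quadrature, never by
calling the Monte Carlo engine, so comparisons against it are genuine
cross-checks: Beer-Lambert ballistic transmission, textbook Fresnel
reflectances, and Henyey-Greenstein moments.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

__all__ = [
    "beer_lambert_reference",
    "fresnel_closed_form",
    "hg_density",
    "hg_moments",
    "hg_cdf_inverse_reference",
]


def beer_lambert_reference(mu_a: float, mu_s: float, d: float) -> float:
    """Unscattered (ballistic) transmission through a slab of thickness d.

    exp(-(mu_a + mu_s) * d): the probability that a photon traverses the
    slab without any interaction.
    """
    if d < 0:
        raise ValueError("thickness must be >= 0")
    return math.exp(-(mu_a + mu_s) * d)


def fresnel_closed_form(theta_i: float, n_i: float, n_t: float):
    """Textbook unpolarized Fresnel reflectance.

    Returns (R_s, R_p, R) at incidence angle ``theta_i`` [rad].  Beyond the
    critical angle all three are 1 (total internal reflection).
    """
    if not (0 <= theta_i < math.pi / 2):
        raise ValueError("incidence angle must be in [0, pi/2)")
    sin_t = n_i / n_t * math.sin(theta_i)
    if sin_t >= 1.0:
        return 1.0, 1.0, 1.0
    theta_t = math.asin(sin_t)
    if theta_i == 0.0:
        r = ((n_i - n_t) / (n_i + n_t)) ** 2
        return r, r, r
    rs = (
        math.sin(theta_i - theta_t) ** 2 / math.sin(theta_i + theta_t) ** 2
    )
    rp = (
        math.tan(theta_i - theta_t) ** 2 / math.tan(theta_i + theta_t) ** 2
    )
    return rs, rp, 0.5 * (rs + rp)


def hg_density(cos_theta, g: float):
    """Henyey-Greenstein density over cos(theta), normalized to 1 on [-1, 1]."""
    c = np.asarray(cos_theta, dtype=float)
    return 0.5 * (1.0 - g * g) / (1.0 + g * g - 2.0 * g * c) ** 1.5


def hg_moments(g: float) -> tuple[float, float]:
    """(E[cos theta], E[cos^2 theta]) of the Henyey-Greenstein distribution.

    The first moment is g identically; the second is obtained by numerical
    quadrature of the density (tolerance 1e-10).
    """
    if not (0 <= g < 1):
        raise ValueError("g must be in [0, 1)")
    second, _ = integrate.quad(
        lambda c: c * c * hg_density(c, g), -1.0, 1.0, epsabs=1e-12, epsrel=1e-12
    )
    return g, second


def hg_cdf_inverse_reference(g: float, u) -> np.ndarray:
    """Closed-form inverse CDF of cos(theta) for Henyey-Greenstein."""
    u = np.asarray(u, dtype=float)
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)
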