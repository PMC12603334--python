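"""Numba-compiled photon-packet transport kernel.

One kernel transports all packets for a run.  It supports multiple weight
channels: channels share every geometric random decision (emission angle,
step lengths, boundary reflections, scattering angles, roulette outcomes)
and differ only in the absorption coefficients used for the packet-weight
update.  This implements exact common-random-number pairing of, e.g.,
systole and diastole (or several melanin / saturation conditions) in a
single transport pass.  Shared paths are only valid when the step length
does not depend on the channel, i.e. when steps are sampled from mu_s
alone ("paper-literal" mode); the "mcml-standard" mode (steps sampled from
mu_t = mu_a + mu_s, the classic unbiased scheme) is restricted to a single
channel per pass.

Weight bookkeeping is exact by construction: for every channel,
specular + absorbed + escaped + residual == launched, where ``residual``
is a signed balance absorbing roulette kills/boosts and cutoff or
event-limit terminations.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["transport"]


@njit(cache=True, inline="always", fastmath=True)
def _interp_sorted(x, xs, ys):
    """Linear interpolation on a sorted grid (clamped at the ends)."""
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    i = np.searchsorted(xs, x)
    x0 = xs[i - 1]
    x1 = xs[i]
    f = (x - x0) / (x1 - x0)
    return ys[i - 1] * (1.0 - f) + ys[i] * f


@njit(cache=True, inline="always", fastmath=True)
def _fresnel(cos_i, n_i, n_t):
    """Unpolarized Fresnel reflectance and transmission-angle cosine.

    Returns (R, cos_t); cos_t = 0 signals total internal reflection.
    """
    if cos_i > 0.99999999:
        r = (n_i - n_t) / (n_i + n_t)
        return r * r, 1.0
    sin_i = math.sqrt(max(0.0, 1.0 - cos_i * cos_i))
    sin_t = n_i / n_t * sin_i
    if sin_t >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t * sin_t)
    rs = (n_i * cos_i - n_t * cos_t) / (n_i * cos_i + n_t * cos_t)
    rp = (n_t * cos_i - n_i * cos_t) / (n_t * cos_i + n_i * cos_t)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True, inline="always", fastmath=True)
def _hg_cos(g, xi):
    """Henyey-Greenstein deflection cosine by inverse-CDF sampling."""
    if abs(g) < 1e-12:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True)
def transport(
    seed,
    n_packets,
    zb,  # (L+1,) depth boundaries [mm]; zb[L] very large (semi-infinite)
    mu_a,  # (L, K) absorption per layer and channel [1/mm]
    mu_s,  # (L,)
    g_arr,  # (L,)
    n_arr,  # (L,) refractive indices
    n_air,
    theta_tab,  # emission CDF lookup: theta grid [rad]
    cdf_tab,  # F(theta)
    tilt_rad,
    det_x,
    det_half,
    ang_tab,  # detector angular-sensitivity grid [rad]
    sens_tab,
    spec_factor,
    step_by_mut,  # True: sample steps from mu_t (single channel only)
    w_thresh,
    m_surv,
    r_max,
    z_max,
    max_events,
):
    L = mu_s.shape[0]
    K = mu_a.shape[1]

    np.random.seed(seed)

    specular = 0.0
    n_rejected = 0
    n_detected = 0
    unscattered_terminal = 0.0
    absorbed = np.zeros((L, K))
    absorbed_det = np.zeros((L, K))
    escaped = np.zeros(K)
    detected_w = np.zeros(K)
    residual = np.zeros(K)

    w = np.empty(K)
    abs_path = np.empty((L, K))

    for _ in range(n_packets):
        # --- emission: theta = F^-1(u), phi uniform ---
        u = np.random.random()
        theta = _interp_sorted(u, cdf_tab, theta_tab)
        phi = 2.0 * math.pi * np.random.random()
        st = math.sin(theta)
        ux = st * math.cos(phi)
        uy = st * math.sin(phi)
        uz = math.cos(theta)
        if tilt_rad != 0.0:
            # rotate about the y-axis: +tilt tips the centroid toward +x
            ct = math.cos(tilt_rad)
            s_t = math.sin(tilt_rad)
            ux, uz = uz * s_t + ux * ct, uz * ct - ux * s_t
        if uz <= 1e-9:
            # grazing/backward in air: does not enter tissue
            specular += 1.0
            n_rejected += 1
            continue

        # --- specular entry (air -> epidermis) ---
        r_spec, cos_t = _fresnel(uz, n_air, n_arr[0])
        specular += r_spec
        w0 = 1.0 - r_spec
        scale = n_air / n_arr[0]
        ux *= scale
        uy *= scale
        uz = cos_t

        x = 0.0
        y = 0.0
        z = 0.0
        layer = 0
        for k in range(K):
            w[k] = w0
        for i in range(L):
            for k in range(K):
                abs_path[i, k] = 0.0
        n_scat = 0
        events = 0
        tau = -math.log(np.random.random())
        alive = True

        while alive:
            events += 1
            if events > max_events:
                for k in range(K):
                    residual[k] += w[k]
                break

            mu = mu_s[layer]
            if step_by_mut:
                mu = mu + mu_a[layer, 0]
            s = tau / mu

            if uz > 0.0:
                db = (zb[layer + 1] - z) / uz
            elif uz < 0.0:
                db = (zb[layer] - z) / uz
            else:
                db = 1e30

            if db < s:
                # --- boundary hit before interaction ---
                x += ux * db
                y += uy * db
                tau -= db * mu
                going_up = uz < 0.0
                z = zb[layer] if going_up else zb[layer + 1]
                if going_up and layer == 0:
                    n_t = n_air
                elif going_up:
                    n_t = n_arr[layer - 1]
                else:
                    n_t = n_arr[layer + 1]
                cos_i = abs(uz)
                r, cos_t = _fresnel(cos_i, n_arr[layer], n_t)
                if np.random.random() > r:
                    # transmitted
                    if going_up and layer == 0:
                        # escape through the top surface into air
                        for k in range(K):
                            escaped[k] += w[k]
                        if (
                            abs(x - det_x) <= det_half
                            and abs(y) <= det_half
                        ):
                            n_detected += 1
                            sens = (
                                _interp_sorted(
                                    math.acos(min(1.0, cos_t)), ang_tab, sens_tab
                                )
                                * spec_factor
                            )
                            for k in range(K):
                                detected_w[k] += w[k] * sens
                            for i in range(L):
                                for k in range(K):
                                    absorbed_det[i, k] += abs_path[i, k]
                        alive = False
                    else:
                        sc = n_arr[layer] / n_t
                        ux *= sc
                        uy *= sc
                        uz = -cos_t if going_up else cos_t
                        layer = layer - 1 if going_up else layer + 1
                        if layer == L - 1 and n_scat == 0 and not going_up:
                            # ballistic weight reaching the terminal layer
                            unscattered_terminal += w[0]
                else:
                    uz = -uz
                continue

            # --- interaction site ---
            x += ux * s
            y += uy * s
            z += uz * s
            if x * x + y * y > r_max * r_max or z > z_max:
                for k in range(K):
                    residual[k] += w[k]
                break

            for k in range(K):
                ma = mu_a[layer, k]
                dw = w[k] * ma / (mu_s[layer] + ma)
                w[k] -= dw
                abs_path[layer, k] += dw
                absorbed[layer, k] += dw
            n_scat += 1

            gl = g_arr[layer]
            cos_sc = _hg_cos(gl, np.random.random())
            sin_sc = math.sqrt(max(0.0, 1.0 - cos_sc * cos_sc))
            phi = 2.0 * math.pi * np.random.random()
            cp = math.cos(phi)
            sp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_sc * cp
                uy = sin_sc * sp
                uz = cos_sc if uz >= 0.0 else -cos_sc
            else:
                den = math.sqrt(1.0 - uz * uz)
                nux = sin_sc * (ux * uz * cp - uy * sp) / den + ux * cos_sc
                nuy = sin_sc * (uy * uz * cp + ux * sp) / den + uy * cos_sc
                nuz = -sin_sc * cp * den + uz * cos_sc
                ux, uy, uz = nux, nuy, nuz
            norm = math.sqrt(ux * ux + uy * uy + uz * uz)
            ux /= norm
            uy /= norm
            uz /= norm

            # --- roulette (gated on the largest channel weight) ---
            wmax = w[0]
            for k in range(1, K):
                if w[k] > wmax:
                    wmax = w[k]
            if wmax < w_thresh:
                if np.random.random() < 1.0 / m_surv:
                    for k in range(K):
                        residual[k] -= w[k] * (m_surv - 1.0)
                        w[k] *= m_surv
                else:
                    for k in range(K):
                        residual[k] += w[k]
                    break

            tau = -math.log(np.random.random())

    return (
        specular,
        n_rejected,
        n_detected,
        absorbed,
        absorbed_det,
        escaped,
        detected_w,
        residual,
        unscattered_terminal,
    )
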