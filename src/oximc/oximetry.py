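"""Pulse-oximetry quantities: PI, RoR, SpO2 calibration, MAE, shot-noise SNR.

The perfusion index PI = (I_dia - I_sys) / I_sys relates the pulsatile
intensity swing to the systolic level.  The ratio of ratios
RoR = PI_red / PI_infrared feeds a quadratic calibration
SpO2 = A*RoR^2 + B*RoR + C fitted by ordinary least squares over a
population of simulated conditions.  SNR follows the Poisson shot-noise
model: with intensities expressed as expected photon counts,
SNR = (I_dia - I_sys) / sqrt(I_dia + I_sys).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .skin_model import ValidationError

__all__ = [
    "PulsePair",
    "CalibrationModel",
    "perfusion_index",
    "ratio_of_ratios",
    "fit_calibration",
    "estimate_spo2",
    "mae",
    "snr",
]


@dataclass(frozen=True)
class PulsePair:
    """Systole/diastole detected intensities for one condition."""

    i_sys: float
    i_dia: float
    count_scale: float = 1.0  # converts intensities to expected photon counts

    def __post_init__(self):
        if self.i_sys < 0 or self.i_dia < 0:
            raise ValidationError("intensities must be >= 0")


def perfusion_index(pair: PulsePair) -> float:
    """PI = (I_dia - I_sys) / I_sys."""
    if pair.i_sys <= 0:
        raise ValidationError("PI undefined for I_sys = 0")
    return (pair.i_dia - pair.i_sys) / pair.i_sys


def ratio_of_ratios(pi_red: float, pi_ir: float) -> float:
    """RoR = PI_red / PI_infrared."""
    if pi_ir == 0:
        raise ValidationError("RoR undefined for PI_ir = 0")
    return pi_red / pi_ir


@dataclass(frozen=True)
class CalibrationModel:
    """Quadratic RoR -> SpO2 map for one (red, infrared) wavelength pair."""

    A: float
    B: float
    C: float
    pair: tuple[float, float]
    n_samples: int = 0
    rmse: float = float("nan")

    def __call__(self, ror):
        return estimate_spo2(self, ror)


def fit_calibration(
    ror: np.ndarray,
    sao2_percent: np.ndarray,
    pair: tuple[float, float] = (float("nan"), float("nan")),
) -> CalibrationModel:
    """Least-squares fit of SaO2 [%] on (RoR^2, RoR, 1).

    Samples with non-finite or non-positive RoR are excluded (RoR is
    undefined when either band's PI is non-positive).  Requires at least
    three distinct RoR values.
    """
    ror = np.asarray(ror, dtype=float)
    sao2 = np.asarray(sao2_percent, dtype=float)
    if ror.shape != sao2.shape:
        raise ValidationError("RoR and SaO2 arrays must have equal length")
    ok = np.isfinite(ror) & np.isfinite(sao2) & (ror > 0)
    ror, sao2 = ror[ok], sao2[ok]
    if len(np.unique(ror)) < 3:
        raise ValidationError("need >= 3 distinct RoR values to fit a quadratic")
    X = np.column_stack([ror**2, ror, np.ones_like(ror)])
    coef, *_ = np.linalg.lstsq(X, sao2, rcond=None)
    resid = sao2 - X @ coef
    return CalibrationModel(
        A=float(coef[0]),
        B=float(coef[1]),
        C=float(coef[2]),
        pair=pair,
        n_samples=int(len(ror)),
        rmse=float(np.sqrt(np.mean(resid**2))),
    )


def estimate_spo2(model: CalibrationModel, ror, *, clamp: bool = False):
    """SpO2 [%] = A*RoR^2 + B*RoR + C (optionally clamped to [0, 100])."""
    ror = np.asarray(ror, dtype=float)
    out = model.A * ror**2 + model.B * ror + model.C
    if clamp:
        out = np.clip(out, 0.0, 100.0)
    if out.ndim == 0:
        return float(out)
    return out


def mae(estimates, truths) -> float:
    """Mean absolute error between SpO2 estimates and true SaO2 [%]."""
    est = np.asarray(estimates, dtype=float)
    tru = np.asarray(truths, dtype=float)
    if est.shape != tru.shape or est.size == 0:
        raise ValidationError("estimates and truths must be equal-length, non-empty")
    return float(np.mean(np.abs(est - tru)))


def snr(
    pair: PulsePair, count_scale: float | None = None, *, db_convention: str = "power"
) -> tuple[float, float]:
    """Shot-noise SNR of the pulsatile component.

    Intensities are scaled to expected photon counts by ``count_scale``
    (the launched packet number of the underlying run by default, taken
    from ``pair.count_scale``), then
    SNR = (I_dia - I_sys)/sqrt(I_dia + I_sys).  Returned in linear units
    and decibels (10*log10 by default; 20*log10 with
    ``db_convention="amplitude"``).  The dB value is NaN for SNR <= 0.
    """
    scale = pair.count_scale if count_scale is None else count_scale
    c_sys = pair.i_sys * scale
    c_dia = pair.i_dia * scale
    if c_sys + c_dia <= 0:
        raise ValidationError("SNR undefined for zero total intensity")
    value = (c_dia - c_sys) / math.sqrt(c_dia + c_sys)
    if value <= 0:
        return value, float("nan")
    factor = 10.0 if db_convention == "power" else 20.0
    return value, factor * math.log10(value)
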