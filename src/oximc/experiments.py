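"""Virtual-cohort parameter sweeps and result aggregation.

A sweep walks the full study grid — wavelengths x source configurations
(LED 0 deg, VCSEL 0/+45/-45 deg) x source-detector distances x melanin
levels x arterial saturations x cardiac phases x cohort seeds — and
produces a tidy long-format table.  For each (wavelength, source, distance,
seed) cell, all physiological conditions are transported as common-path
weight channels of one kernel pass, so systole/diastole pairs (and melanin
or saturation contrasts) are exactly matched.

Aggregations reproduce the study's derived quantities: PI summaries per
melanin/saturation level, the PI change from 70 % to 100 % SaO2 and its
spread between melanin extremes, pooled population SpO2 calibrations per
wavelength pair, MAE stratifications, and paired Wilcoxon comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import oximetry
from .beam_sources import SourceConfig, default_detector
from .mc_engine import (
    PAPER_LITERAL,
    TransportParams,
    epidermis_absorption_fraction,
    run_paired_simulation,
)
from .oximetry import CalibrationModel, PulsePair, fit_calibration
from .skin_model import DIASTOLE, SYSTOLE, PhysioState, ValidationError, build_tissue_stack

__all__ = [
    "ParameterGrid",
    "SOURCE_CONFIGS",
    "profile_for",
    "run_sweep",
    "pair_phases",
    "aggregate_pi",
    "pi_change_metric",
    "build_oximetry_samples",
    "fit_population_calibrations",
    "evaluate_spo2",
    "error_comparison",
    "report_tables",
]

RED_WAVELENGTHS = (624.0, 660.0)
IR_WAVELENGTHS = (850.0, 940.0)
SOURCE_CONFIGS = (("LED", 0.0), ("VCSEL", 0.0), ("VCSEL", 45.0), ("VCSEL", -45.0))
WAVELENGTH_PAIRS = tuple(itertools.product(RED_WAVELENGTHS, IR_WAVELENGTHS))

#: transport defaults for sweeps: steps sampled from mu_s so that all
#: physiological conditions can share photon paths as weight channels
SWEEP_PARAMS = TransportParams(step_mode=PAPER_LITERAL)


def profile_for(kind: str, wavelength: float) -> str:
    """Map a source kind (LED/VCSEL) and wavelength to a bundled profile id."""
    band = "R" if wavelength < 700 else "IR"
    return f"{kind}_{band}"


@dataclass(frozen=True)
class ParameterGrid:
    """The study grid; defaults are the full design space."""

    wavelengths: tuple = (624.0, 660.0, 850.0, 940.0)
    source_configs: tuple = SOURCE_CONFIGS
    sdd_mm: tuple = tuple(float(d) for d in range(2, 10))
    c_mel: tuple = (0.0255, 0.055, 0.105, 0.155, 0.205, 0.255, 0.305)
    sao2: tuple = (0.70, 0.80, 0.90, 1.00)
    n_seeds: int = 25
    n_packets: int = 1_000_000
    systolic_gain: float = 1.10

    def __post_init__(self):
        for axis in ("wavelengths", "source_configs", "sdd_mm", "c_mel", "sao2"):
            if len(getattr(self, axis)) == 0:
                raise ValidationError(f"grid axis {axis} must be non-empty")
        for kind, tilt in self.source_configs:
            if kind == "LED" and tilt != 0.0:
                raise ValidationError("LED sources are only simulated at 0 deg")

    @property
    def n_rows(self) -> int:
        """Number of sweep rows: grid cells x 2 cardiac phases."""
        return (
            len(self.wavelengths)
            * len(self.source_configs)
            * len(self.sdd_mm)
            * len(self.c_mel)
            * len(self.sao2)
            * 2
            * self.n_seeds
        )


def _run_seed(base_seed: int, *coords) -> int:
    """Stable per-cell seed: depends only on the grid coordinates."""
    key = [int(base_seed)] + [
        int(round(float(c) * 1000)) % (2**32) for c in coords
    ]
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def run_sweep(
    grid: ParameterGrid,
    params: TransportParams | None = None,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the grid; returns one row per (grid cell, cardiac phase).

    Deterministic given (grid, base_seed): each transport cell derives its
    RNG seed from its own grid coordinates, so re-running any subset of the
    grid reproduces identical rows.
    """
    params = params or SWEEP_PARAMS
    rows = []
    cells = list(
        itertools.product(
            grid.wavelengths, grid.source_configs, grid.sdd_mm, range(grid.n_seeds)
        )
    )
    conditions = [
        (c_mel, sao2, phase)
        for c_mel in grid.c_mel
        for sao2 in grid.sao2
        for phase in (DIASTOLE, SYSTOLE)
    ]
    for idx, (wl, (kind, tilt), sdd, seed_idx) in enumerate(cells):
        if progress and idx % 10 == 0:
            print(f"sweep cell {idx + 1}/{len(cells)}", flush=True)
        source = SourceConfig(profile_for(kind, wl), wl, tilt_deg=tilt)
        detector = default_detector(sdd)
        stacks = [
            build_tissue_stack(
                PhysioState(sao2, c_mel, phase, grid.systolic_gain), wl
            )
            for (c_mel, sao2, phase) in conditions
        ]
        run_seed = _run_seed(base_seed, wl, tilt, 1 if kind == "LED" else 2, sdd, seed_idx)
        try:
            results = run_paired_simulation(
                source, detector, stacks, grid.n_packets, run_seed, params
            )
        except ValidationError as err:  # pragma: no cover - defensive
            print(f"sweep cell failed ({wl} nm {kind} {tilt} {sdd} mm): {err}")
            continue
        for (c_mel, sao2, phase), res in zip(conditions, results):
            t = res.tally
            rows.append(
                {
                    "wavelength": wl,
                    "profile": kind,
                    "tilt": tilt,
                    "sdd_mm": sdd,
                    "c_mel": c_mel,
                    "sao2": sao2,
                    "seed": seed_idx,
                    "phase": phase,
                    "intensity": res.intensity,
                    "n_detected": t.n_detected,
                    "n_launched": t.n_launched,
                    "epidermis_fraction": (
                        epidermis_absorption_fraction(t) if t.n_detected else np.nan
                    ),
                    "audit_error": t.audit_error(),
                }
            )
    return pd.DataFrame(rows)


_COORDS = ["wavelength", "profile", "tilt", "sdd_mm", "c_mel", "sao2", "seed"]


def pair_phases(sweep: pd.DataFrame) -> pd.DataFrame:
    """Join systole/diastole rows into one row per condition with PI and SNR."""
    dia = sweep[sweep["phase"] == DIASTOLE].set_index(_COORDS)
    sys_ = sweep[sweep["phase"] == SYSTOLE].set_index(_COORDS)
    common = dia.index.intersection(sys_.index)
    missing = len(dia) + len(sys_) - 2 * len(common)
    if missing:
        print(f"pair_phases: skipped {missing} unpaired rows")
    dia, sys_ = dia.loc[common], sys_.loc[common]
    out = pd.DataFrame(index=common)
    out["i_dia"] = dia["intensity"]
    out["i_sys"] = sys_["intensity"]
    out["n_detected"] = dia["n_detected"]
    out["n_launched"] = dia["n_launched"]
    out["epidermis_fraction"] = dia["epidermis_fraction"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["pi"] = (out["i_dia"] - out["i_sys"]) / out["i_sys"]
    counts_dia = out["i_dia"] * out["n_launched"]
    counts_sys = out["i_sys"] * out["n_launched"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["snr"] = (counts_dia - counts_sys) / np.sqrt(counts_dia + counts_sys)
        out["snr_db"] = 10.0 * np.log10(out["snr"].where(out["snr"] > 0))
    return out.reset_index()


def aggregate_pi(
    paired: pd.DataFrame, group_by=("wavelength", "c_mel", "sao2")
) -> pd.DataFrame:
    """Mean and standard deviation of PI per group (defaults average over
    source configurations, distances and seeds)."""
    grouped = paired.groupby(list(group_by))["pi"]
    out = grouped.agg(pi_mean="mean", pi_std="std", n="count").reset_index()
    return out


def pi_change_metric(
    paired: pd.DataFrame,
    wavelength: float,
    profile: str,
    tilt: float,
    sao2_low: float = 0.70,
    sao2_high: float = 1.00,
) -> tuple[pd.Series, float]:
    """Mean PI change from low to high SaO2 per melanin level, and its spread.

    The change is PI(SaO2 low) - PI(SaO2 high), averaged over distances and
    seeds; the spread is the change at the lowest melanin level minus the
    change at the highest.
    """
    sub = paired[
        (paired["wavelength"] == wavelength)
        & (paired["profile"] == profile)
        & (paired["tilt"] == tilt)
    ]
    lo = sub[np.isclose(sub["sao2"], sao2_low)]
    hi = sub[np.isclose(sub["sao2"], sao2_high)]
    if lo.empty or hi.empty:
        raise ValidationError("both SaO2 endpoints must be present in the table")
    key = ["c_mel", "sdd_mm", "seed"]
    merged = lo.set_index(key)[["pi"]].join(
        hi.set_index(key)[["pi"]], lsuffix="_lo", rsuffix="_hi", how="inner"
    )
    change = (
        (merged["pi_lo"] - merged["pi_hi"]).groupby(level="c_mel").mean()
    )
    spread = float(change.loc[change.index.min()] - change.loc[change.index.max()])
    return change, spread


def build_oximetry_samples(
    paired: pd.DataFrame, pairs=WAVELENGTH_PAIRS
) -> pd.DataFrame:
    """RoR samples per wavelength pair, joined on shared grid coordinates."""
    key = ["profile", "tilt", "sdd_mm", "c_mel", "sao2", "seed"]
    frames = []
    for red, ir in pairs:
        r = paired[paired["wavelength"] == red].set_index(key)
        i = paired[paired["wavelength"] == ir].set_index(key)
        common = r.index.intersection(i.index)
        df = pd.DataFrame(index=common)
        df["pi_red"] = r.loc[common, "pi"]
        df["pi_ir"] = i.loc[common, "pi"]
        with np.errstate(divide="ignore", invalid="ignore"):
            df["ror"] = df["pi_red"] / df["pi_ir"]
        # RoR is undefined when either band's PI is non-positive
        bad = (df["pi_red"] <= 0) | (df["pi_ir"] <= 0)
        if bad.any():
            print(f"pair {red}/{ir}: excluded {int(bad.sum())} non-positive-PI samples")
        df.loc[bad, "ror"] = np.nan
        df["red"] = red
        df["ir"] = ir
        frames.append(df.reset_index())
    return pd.concat(frames, ignore_index=True)


def fit_population_calibrations(
    samples: pd.DataFrame,
) -> dict[tuple[float, float], CalibrationModel]:
    """One pooled quadratic calibration per wavelength pair (all melanin
    levels, geometries, distances and seeds together)."""
    models = {}
    for (red, ir), sub in samples.groupby(["red", "ir"]):
        ok = sub["ror"].notna()
        models[(red, ir)] = fit_calibration(
            sub.loc[ok, "ror"].to_numpy(),
            sub.loc[ok, "sao2"].to_numpy() * 100.0,
            pair=(red, ir),
        )
    return models


def evaluate_spo2(
    samples: pd.DataFrame, models: dict[tuple[float, float], CalibrationModel]
) -> pd.DataFrame:
    """Apply each pair's calibration; adds spo2_est and abs_err columns [%]."""
    out = samples.copy()
    out["spo2_est"] = np.nan
    for (red, ir), model in models.items():
        m = (out["red"] == red) & (out["ir"] == ir) & out["ror"].notna()
        out.loc[m, "spo2_est"] = model(out.loc[m, "ror"].to_numpy())
    out["abs_err"] = np.abs(out["spo2_est"] - out["sao2"] * 100.0)
    return out


def error_comparison(errors_a, errors_b) -> dict:
    """Paired comparison of two error samples aligned on grid coordinates.

    Returns the one-sided Wilcoxon signed-rank test of a > b together with
    Shapiro-Wilk normality p-values of the paired differences (the gate that
    motivates the rank test).  All-zero differences leave the test
    undefined (p = NaN).
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.size == 0:
        raise ValidationError("paired samples must be equal-length and non-empty")
    diff = a - b
    out = {"n": int(a.size), "mean_diff": float(diff.mean())}
    if np.all(diff == 0):
        out.update(wilcoxon_stat=np.nan, wilcoxon_p=np.nan)
    else:
        res = stats.wilcoxon(a, b, alternative="greater")
        out.update(wilcoxon_stat=float(res.statistic), wilcoxon_p=float(res.pvalue))
    if a.size >= 3 and np.ptp(diff) > 0:
        out["shapiro_p"] = float(stats.shapiro(diff).pvalue)
    else:
        out["shapiro_p"] = np.nan
    return out


def report_tables(
    paired: pd.DataFrame,
    models: dict | None = None,
    outdir: str | None = None,
) -> dict[str, pd.DataFrame]:
    """Tidy long-format result tables (PI summaries, calibration constants,
    MAE by distance); optionally written as CSV under ``outdir``."""
    tables: dict[str, pd.DataFrame] = {}
    tables["pi_summary"] = aggregate_pi(paired)
    if models:
        tables["calibration"] = pd.DataFrame(
            [
                {
                    "red": red,
                    "ir": ir,
                    "A": m.A,
                    "B": m.B,
                    "C": m.C,
                    "n_samples": m.n_samples,
                    "rmse": m.rmse,
                }
                for (red, ir), m in models.items()
            ]
        )
        samples = build_oximetry_samples(paired, pairs=list(models))
        evaluated = evaluate_spo2(samples, models)
        tables["mae_by_distance"] = (
            evaluated.groupby(["red", "ir", "profile", "tilt", "sdd_mm"])["abs_err"]
            .mean()
            .rename("mae")
            .reset_index()
        )
    else:
        print("report_tables: no calibration models, SpO2 tables omitted")
    if outdir is not None:
        import pathlib

        p = pathlib.Path(outdir)
        p.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(p / f"{name}.csv", index=False)
    return tables
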