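"""Layered skin tissue model and per-layer optical properties.

The skin is represented as a stack of plane-parallel layers (epidermis,
four vascular dermal layers, hypodermis) over a semi-infinite muscle layer.
Each layer's absorption coefficient is mixed from chromophore spectra
(oxy-/deoxyhemoglobin, water, melanin, and a small baseline term) according
to its volume fractions, the arterial oxygen saturation SaO2, the epidermal
melanin volume fraction C_Mel, and the cardiac phase.  Systole is modelled
as a relative increase of the blood volume fraction of the pulsatile layers.

Scattering coefficients and anisotropy factors are tabulated per layer and
wavelength in the bundled ``scattering.csv``; all tables are editable CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from io import StringIO

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "LayerSpec",
    "PhysioState",
    "OpticalProperties",
    "TissueStack",
    "SkinTables",
    "load_default_tables",
    "mixed_absorption",
    "pulsatile_blood_fraction",
    "build_tissue_stack",
]

SYSTOLE = "systole"
DIASTOLE = "diastole"

DEFAULT_SYSTOLIC_GAIN = 1.10


def _read_bundled(name: str) -> pd.DataFrame:
    text = resources.files("oximc.data").joinpath(name).read_text()
    return pd.read_csv(StringIO(text), comment="#")


class ConfigurationError(ValueError):
    """A required table row or configuration entry is missing."""


class ValidationError(ValueError):
    """An input violates a physical or structural invariant."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Absorption coefficients [1/mm] of the pure chromophores, per wavelength."""

    table: pd.DataFrame  # indexed by wavelength [nm]

    def __post_init__(self):
        t = self.table
        if (t.to_numpy() < 0).any():
            raise ValidationError("chromophore absorption coefficients must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChromophoreTable":
        df = df.set_index("wavelength") if "wavelength" in df.columns else df
        return cls(df.astype(float))

    def row(self, wavelength: float) -> pd.Series:
        if wavelength not in self.table.index:
            raise ConfigurationError(
                f"no chromophore data for wavelength {wavelength} nm; "
                f"available: {list(self.table.index)}"
            )
        return self.table.loc[wavelength]

    @property
    def wavelengths(self) -> list[float]:
        return list(self.table.index)


@dataclass(frozen=True)
class LayerSpec:
    """Geometry and composition of one skin layer (Table-style row)."""

    name: str
    n: float
    d_t: float  # thickness [mm]; inf for the terminal layer
    C_b: float  # blood volume fraction
    C_w: float  # water volume fraction
    v_d: float  # vessel diameter [mm]; stored, unused unless vessel packing enabled
    pulsatile: bool
    mu_a_direct: dict | None = None  # wavelength -> mu_a for layers without mixing

    def __post_init__(self):
        if self.n < 1:
            raise ValidationError(f"{self.name}: refractive index must be >= 1")
        if not (self.d_t > 0):
            raise ValidationError(f"{self.name}: thickness must be > 0")
        if not (0 <= self.C_b <= 1 and 0 <= self.C_w <= 1):
            raise ValidationError(f"{self.name}: volume fractions must be in [0, 1]")


@dataclass(frozen=True)
class PhysioState:
    """Physiological condition resolved at simulation time.

    SaO2 is the arterial oxygen saturation (fraction), C_Mel the melanin
    (melanosome) volume fraction of the epidermis.  ``systolic_gain`` is the
    multiplier applied to the blood volume fraction of pulsatile layers
    during systole; the default models a 10 % relative increase.
    """

    sao2: float
    c_mel: float
    phase: str = DIASTOLE
    systolic_gain: float = DEFAULT_SYSTOLIC_GAIN

    def __post_init__(self):
        if not (0.0 <= self.sao2 <= 1.0):
            raise ValidationError("SaO2 must be a fraction in [0, 1]")
        if not (0.0 <= self.c_mel <= 1.0):
            raise ValidationError("C_Mel must be a fraction in [0, 1]")
        if self.phase not in (SYSTOLE, DIASTOLE):
            raise ValidationError(f"phase must be '{SYSTOLE}' or '{DIASTOLE}'")
        if not self.systolic_gain > 1.0:
            raise ValidationError("systolic_gain must be > 1")

    def with_phase(self, phase: str) -> "PhysioState":
        return replace(self, phase=phase)


@dataclass(frozen=True)
class OpticalProperties:
    mu_a: float  # [1/mm]
    mu_s: float  # [1/mm]
    g: float
    n: float
    thickness: float  # [mm]

    def __post_init__(self):
        if self.mu_a < 0 or not self.mu_s > 0 or not (0 <= self.g < 1) or self.n < 1:
            raise ValidationError("optical properties out of physical range")


@dataclass(frozen=True)
class TissueStack:
    """Resolved layer stack, surface downward; the last layer is semi-infinite."""

    layers: tuple[LayerSpec, ...]
    properties: tuple[OpticalProperties, ...]
    wavelength: float
    state: PhysioState

    def __post_init__(self):
        if len(self.layers) != len(self.properties):
            raise ValidationError("layers/properties length mismatch")
        if not math.isinf(self.properties[-1].thickness):
            raise ValidationError("terminal layer must be semi-infinite")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.layers]

    @property
    def epidermis_index(self) -> int:
        return self.names.index("epidermis")

    @property
    def boundaries(self) -> np.ndarray:
        """Depth boundaries [mm]: z[0]=0 .. z[L] (inf below terminal layer)."""
        d = np.array([p.thickness for p in self.properties])
        return np.concatenate([[0.0], np.cumsum(d)])

    def arrays(self):
        """Per-layer property arrays (mu_a, mu_s, g, n) for the transport kernel."""
        p = self.properties
        return (
            np.array([q.mu_a for q in p]),
            np.array([q.mu_s for q in p]),
            np.array([q.g for q in p]),
            np.array([q.n for q in p]),
        )


@dataclass(frozen=True)
class SkinTables:
    """Bundle of the editable data tables defining the skin model."""

    chromophores: ChromophoreTable
    layers: tuple[LayerSpec, ...]
    scattering: pd.DataFrame  # columns: layer, wavelength, mu_s, g
    baseline_closure: bool = True
    vessel_packing: bool = False

    def scattering_for(self, layer: str, wavelength: float) -> tuple[float, float]:
        m = self.scattering[
            (self.scattering["layer"] == layer)
            & (self.scattering["wavelength"] == wavelength)
        ]
        if len(m) != 1:
            raise ConfigurationError(
                f"missing scattering entry for layer={layer}, wavelength={wavelength}"
            )
        row = m.iloc[0]
        return float(row["mu_s"]), float(row["g"])


_DEFAULT_TABLES: SkinTables | None = None


def load_default_tables() -> SkinTables:
    """Load the bundled chromophore/layer/scattering tables (cached)."""
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        chromo = ChromophoreTable.from_frame(_read_bundled("chromophores.csv"))
        ldf = _read_bundled("layers.csv")
        sdf = _read_bundled("scattering.csv")
        layers = []
        for _, r in ldf.iterrows():
            direct = None
            if pd.isna(r["C_b"]):  # composition-free layer: direct absorption table
                sub = sdf[(sdf["layer"] == r["name"]) & sdf["mu_a_direct"].notna()]
                direct = dict(zip(sub["wavelength"], sub["mu_a_direct"]))
            layers.append(
                LayerSpec(
                    name=str(r["name"]),
                    n=float(r["n"]),
                    d_t=float(r["d_t_mm"]),
                    C_b=0.0 if pd.isna(r["C_b"]) else float(r["C_b"]),
                    C_w=0.0 if pd.isna(r["C_w"]) else float(r["C_w"]),
                    v_d=float(r["v_d_mm"]),
                    pulsatile=str(r["pulsatile"]).strip().lower() in ("yes", "true", "1"),
                    mu_a_direct=direct,
                )
            )
        _DEFAULT_TABLES = SkinTables(chromo, tuple(layers), sdf)
    return _DEFAULT_TABLES


def pulsatile_blood_fraction(layer: LayerSpec, state: PhysioState) -> float:
    """Effective blood volume fraction of ``layer`` in the given cardiac phase.

    Diastole leaves C_b unchanged; systole multiplies C_b of pulsatile layers
    by ``state.systolic_gain``.  Non-pulsatile layers (epidermis) are never
    modulated.
    """
    if state.phase == SYSTOLE and layer.pulsatile:
        return layer.C_b * state.systolic_gain
    return layer.C_b


def _vessel_packing_factor(mu_a_blood: float, v_d: float) -> float:
    """Pigment-packing correction for blood confined to vessels of diameter v_d.

    C_pack = (1 - exp(-2 mu_a r)) / (2 mu_a r), the standard correction for
    absorber confinement; tends to 1 for small vessels or weak absorption.
    """
    x = mu_a_blood * v_d  # 2 * mu_a * r with r = v_d / 2
    if x <= 0:
        return 1.0
    return float(-math.expm1(-x) / x)


def mixed_absorption(
    layer: LayerSpec,
    chromo: ChromophoreTable,
    state: PhysioState,
    wavelength: float,
    *,
    epidermis: bool | None = None,
    baseline_closure: bool = True,
    vessel_packing: bool = False,
) -> float:
    """Total absorption coefficient [1/mm] of one layer.

    mu_a = C_b_eff * (SaO2*mu_a_O2Hb + (1-SaO2)*mu_a_HHb)
         + C_w * mu_a_water
         + C_Mel * mu_a_melanin              (epidermis only)
         + (1 - C_b_eff - C_w - C_Mel[epi]) * mu_a_baseline

    The last term (volume-fraction closure onto the baseline spectrum) can be
    disabled with ``baseline_closure=False``, in which case the baseline term
    is omitted entirely.  Layers carrying a direct absorption table (muscle)
    bypass the mixing.
    """
    if layer.mu_a_direct is not None:
        if wavelength not in layer.mu_a_direct:
            raise ConfigurationError(
                f"no direct mu_a for layer {layer.name} at {wavelength} nm"
            )
        return float(layer.mu_a_direct[wavelength])

    c = chromo.row(wavelength)
    is_epi = layer.name == "epidermis" if epidermis is None else epidermis
    c_b = pulsatile_blood_fraction(layer, state)
    c_mel = state.c_mel if is_epi else 0.0
    remaining = 1.0 - c_b - layer.C_w - c_mel
    if remaining < 0:
        raise ValidationError(
            f"{layer.name}: volume fractions sum to more than 1 "
            f"(C_b_eff={c_b:.4f}, C_w={layer.C_w}, C_Mel={c_mel})"
        )
    mu_blood = state.sao2 * c["mu_a_O2Hb"] + (1.0 - state.sao2) * c["mu_a_HHb"]
    if vessel_packing and layer.v_d > 0:
        mu_blood *= _vessel_packing_factor(mu_blood, layer.v_d)
    mu_a = c_b * mu_blood + layer.C_w * c["mu_a_water"] + c_mel * c["mu_a_melanin"]
    if baseline_closure:
        mu_a += remaining * c["mu_a_baseline"]
    return float(mu_a)


def build_tissue_stack(
    state: PhysioState,
    wavelength: float,
    tables: SkinTables | None = None,
) -> TissueStack:
    """Resolve the full layer stack to optical properties for one condition.

    The stack has the six skin layers plus the terminal semi-infinite muscle
    layer.  A systole stack differs from the matching diastole stack only in
    the absorption coefficients of the pulsatile layers.
    """
    tables = tables or load_default_tables()
    props = []
    for spec in tables.layers:
        mu_s, g = tables.scattering_for(spec.name, wavelength)
        mu_a = mixed_absorption(
            spec,
            tables.chromophores,
            state,
            wavelength,
            baseline_closure=tables.baseline_closure,
            vessel_packing=tables.vessel_packing,
        )
        props.append(
            OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=spec.n, thickness=spec.d_t)
        )
    return TissueStack(
        layers=tuple(tables.layers),
        properties=tuple(props),
        wavelength=wavelength,
        state=state,
    )
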