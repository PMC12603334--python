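import math

import numpy as np
import pytest

from oximc.beam_sources import BeamProfile, DetectorModel, SourceConfig, normalize_and_cdf
from oximc.mc_engine import TransportParams, run_paired_simulation, run_photon_simulation
from oximc.skin_model import (
    DIASTOLE,
    SYSTOLE,
    LayerSpec,
    OpticalProperties,
    PhysioState,
    TissueStack,
    build_tissue_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pencil_beam() -> BeamProfile:
    """Near-delta beam along the surface normal (all mass in the first bin)."""
    theta = np.array([0.0, 1e-6, 2e-6])
    return normalize_and_cdf(theta, np.array([1.0, 1.0, 0.0]), profile_id="pencil")


def single_layer_stack(mu_a, mu_s, g=0.0, n=1.0) -> TissueStack:
    """Homogeneous semi-infinite medium (index-matched to air by default)."""
    spec = LayerSpec("medium", n=n, d_t=math.inf, C_b=0.0, C_w=0.0, v_d=0.0,
                     pulsatile=False)
    prop = OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n, thickness=math.inf)
    state = PhysioState(1.0, 0.0255)
    return TissueStack(layers=(spec,), properties=(prop,), wavelength=660.0,
                       state=state)


def slab_over_sink_stack(d, mu_a, mu_s, g=0.0, n=1.0,
                         sink_mu_a=5.0, sink_mu_s=5.0) -> TissueStack:
    """Finite slab over a semi-infinite absorbing terminal layer, all
    index-matched (used for ballistic-transmission oracles)."""
    state = PhysioState(1.0, 0.0255)
    slab = LayerSpec("slab", n=n, d_t=d, C_b=0.0, C_w=0.0, v_d=0.0, pulsatile=False)
    sink = LayerSpec("sink", n=n, d_t=math.inf, C_b=0.0, C_w=0.0, v_d=0.0,
                     pulsatile=False)
    props = (
        OpticalProperties(mu_a=mu_a, mu_s=mu_s, g=g, n=n, thickness=d),
        OpticalProperties(mu_a=sink_mu_a, mu_s=sink_mu_s, g=g, n=n,
                          thickness=math.inf),
    )
    return TissueStack(layers=(slab, sink), properties=props, wavelength=660.0,
                       state=state)


def wide_detector(sdd=0.0, half=1e4) -> DetectorModel:
    """Detector covering (almost) the whole surface with unit sensitivity."""
    return DetectorModel(
        center=(sdd, 0.0),
        half_width=half,
        angle_deg=np.array([0.0, 90.0]),
        angular_sensitivity=np.array([1.0, 1.0]),
    )


@pytest.fixture(scope="session")
def paired_red_run():
    """Shared paired systole/diastole run at 624 nm, VCSEL 0 deg, 4 mm."""
    from oximc.beam_sources import default_detector

    source = SourceConfig("VCSEL_R", 624.0)
    det = default_detector(4.0)
    params = TransportParams(step_mode="paper-literal")
    stacks = [
        build_tissue_stack(PhysioState(0.70, 0.0255, ph), 624.0)
        for ph in (DIASTOLE, SYSTOLE)
    ]
    return run_paired_simulation(source, det, stacks, 60_000, 7, params)
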