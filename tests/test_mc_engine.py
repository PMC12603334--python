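import math

import numpy as np
import pytest
from scipy import stats

from oximc.beam_sources import SourceConfig, default_detector
from oximc.mc_engine import (
    DetectionTally,
    TransportParams,
    absorb,
    epidermis_absorption_fraction,
    fresnel_boundary,
    hg_scatter,
    roulette,
    run_paired_simulation,
    run_photon_simulation,
    sample_step,
    specular_entry,
)
from oximc.skin_model import DIASTOLE, SYSTOLE, PhysioState, ValidationError, build_tissue_stack
from oximc.validation import beer_lambert_reference, fresnel_closed_form, hg_density

from conftest import pencil_beam, single_layer_stack, slab_over_sink_stack, wide_detector


# ---------------------------------------------------------------- primitives

def test_specular_entry_normal_incidence():
    r, w, d = specular_entry(np.array([0.0, 0.0, 1.0]), 1.0, 1.33)
    assert r == pytest.approx(((1 - 1.33) / (1 + 1.33)) ** 2, rel=1e-9)
    assert w == pytest.approx(1 - r)
    np.testing.assert_allclose(d, [0, 0, 1], atol=1e-12)


def test_specular_entry_index_matched():
    direction = np.array([0.3, 0.1, 0.9])
    direction /= np.linalg.norm(direction)
    r, w, d = specular_entry(direction, 1.33, 1.33)
    assert r == 0.0 and w == 1.0
    np.testing.assert_allclose(d, direction, atol=1e-12)


def test_specular_entry_45deg_matches_closed_form():
    th = math.radians(45)
    direction = np.array([math.sin(th), 0.0, math.cos(th)])
    r, _, d = specular_entry(direction, 1.0, 1.33)
    rs, rp, ref = fresnel_closed_form(th, 1.0, 1.33)
    assert r == pytest.approx(ref, rel=1e-9)
    # refraction obeys Snell's law and preserves the norm
    assert d[0] == pytest.approx(math.sin(th) / 1.33, rel=1e-12)
    assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-12)


def test_specular_entry_rejects_grazing():
    with pytest.raises(ValidationError):
        specular_entry(np.array([1.0, 0.0, 0.0]), 1.0, 1.4)


def test_sample_step_deterministic_value():
    class FixedRng:
        def random(self):
            return 1.0 - math.exp(-1.0)  # xi = e^-1

    assert sample_step(10.0, FixedRng()) == pytest.approx(0.1, rel=1e-12)
    with pytest.raises(ValidationError):
        sample_step(0.0, np.random.default_rng(0))


def test_sample_step_mean(rng):
    n = 200_000
    draws = np.array([sample_step(5.0, rng) for _ in range(n)])
    se = draws.std(ddof=1) / math.sqrt(n)
    assert abs(draws.mean() - 0.2) < 3 * se


def test_fresnel_boundary_branches(rng):
    # sub-critical: matches the sin/tan closed form
    ok, theta_t = fresnel_boundary(math.radians(30), 1.33, 1.40, rng)
    if ok:
        assert theta_t == pytest.approx(
            math.asin(1.33 / 1.40 * math.sin(math.radians(30))), rel=1e-12
        )
    # total internal reflection: always reflected
    for _ in range(50):
        ok, theta_out = fresnel_boundary(math.radians(60), 1.44, 1.0, rng)
        assert not ok and theta_out == pytest.approx(math.radians(60))


def test_fresnel_boundary_transmission_frequency(rng):
    """The stochastic decision transmits with probability 1 - R."""
    theta, n_i, n_t = math.radians(40), 1.40, 1.37
    _, _, r = fresnel_closed_form(theta, n_i, n_t)
    n = 50_000
    hits = sum(fresnel_boundary(theta, n_i, n_t, rng)[0] for _ in range(n))
    se = math.sqrt(r * (1 - r) / n)
    assert abs(hits / n - (1 - r)) < 4 * se


@pytest.mark.parametrize("g", [0.0, 0.9])
def test_hg_scatter_first_moment(g, rng):
    n = 200_000
    cos = np.array([math.cos(hg_scatter(g, rng)[0]) for _ in range(n)])
    se = cos.std(ddof=1) / math.sqrt(n)
    assert abs(cos.mean() - g) < 3 * se


def test_hg_scatter_density_chi2():
    """Histogram of sampled cos(theta) vs the phase-function density."""
    g = 0.7
    n = 200_000
    rng = np.random.default_rng(7)
    cos = np.array([math.cos(hg_scatter(g, rng)[0]) for _ in range(n)])
    edges = np.linspace(-1, 1, 21)
    observed, _ = np.histogram(cos, bins=edges)
    grid = np.linspace(-1, 1, 4001)
    dens = hg_density(grid, g)
    cdf = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    probs = np.diff(np.interp(edges, grid, cdf))
    result = stats.chisquare(observed, probs * n)
    assert result.pvalue > 0.01


def test_hg_scatter_rejects_bad_g(rng):
    with pytest.raises(ValidationError):
        hg_scatter(1.0, rng)


def test_absorb_direct_and_identity():
    w, dw = absorb(1.0, 1.0, 9.0)
    assert w == pytest.approx(0.9) and dw == pytest.approx(0.1)
    w, dw = absorb(0.5, 0.0, 9.0)
    assert w == 0.5 and dw == 0.0


def test_absorb_geometric_ledger():
    """N consecutive events: w = albedo^N and the ledger sums to 1 - w."""
    mu_a, mu_s, n = 0.7, 6.3, 25
    w, total = 1.0, 0.0
    for _ in range(n):
        w, dw = absorb(w, mu_a, mu_s)
        total += dw
    assert w == pytest.approx((mu_s / (mu_s + mu_a)) ** n, rel=1e-12)
    assert total == pytest.approx(1.0 - w, rel=1e-12)


def test_roulette_rules(rng):
    assert roulette(0.5, 1e-4, 10.0, rng) == 0.5  # above threshold: untouched
    out = roulette(5e-5, 1e-4, 10.0, rng)
    assert out in (0.0, pytest.approx(5e-4))


def test_roulette_unbiased(rng):
    w0, n = 3e-5, 100_000
    outcomes = np.array([roulette(w0, 1e-4, 10.0, rng) for _ in range(n)])
    se = outcomes.std(ddof=1) / math.sqrt(n)
    assert abs(outcomes.mean() - w0) < 3 * se


# ----------------------------------------------------------------- transport

def _pencil_source(wavelength=660.0):
    return SourceConfig("custom", wavelength, custom_profile=pencil_beam())


def test_no_absorption_semi_infinite_all_weight_escapes():
    """With mu_a = 0 and matched indices, (almost) all weight re-emerges;
    the tiny deficit is the documented depth-cutoff truncation."""
    stack = single_layer_stack(mu_a=0.0, mu_s=20.0)
    params = TransportParams(
        step_mode="mcml-standard", r_max_mm=1e6, z_max_mm=100.0,
        max_events=10_000_000,
    )
    res = run_photon_simulation(
        _pencil_source(), wide_detector(), stack, 20_000, 11, params
    )
    t = res.tally
    assert t.specular_weight == 0.0
    assert t.escaped_weight / t.n_launched > 0.999
    assert t.audit_error() < 1e-6


def test_ballistic_transmission_matches_beer_lambert():
    """Weight crossing a two-layer slab without scattering follows
    exp(-mu_t * d) in mcml-standard mode (multi-boundary step rescaling)."""
    d1 = 0.12
    stack = slab_over_sink_stack(d1, mu_a=2.0, mu_s=3.0)
    params = TransportParams(step_mode="mcml-standard")
    n = 50_000
    res = run_photon_simulation(
        _pencil_source(), wide_detector(), stack, n, 4, params
    )
    p = beer_lambert_reference(2.0, 3.0, d1)
    frac = res.tally.unscattered_terminal_weight / res.tally.n_launched
    se = math.sqrt(p * (1 - p) / n)
    assert abs(frac - p) < 3 * se


def test_run_determinism_bitwise():
    stack = build_tissue_stack(PhysioState(0.9, 0.105), 660.0)
    src = SourceConfig("VCSEL_R", 660.0)
    det = default_detector(3.0)
    a = run_photon_simulation(src, det, stack, 20_000, 99)
    b = run_photon_simulation(src, det, stack, 20_000, 99)
    assert a.tally.detected_weight == b.tally.detected_weight
    assert a.tally.n_detected == b.tally.n_detected
    assert np.array_equal(a.tally.absorbed_by_layer, b.tally.absorbed_by_layer)
    assert np.array_equal(
        a.tally.absorbed_detected_by_layer, b.tally.absorbed_detected_by_layer
    )
    assert a.tally.residual_weight == b.tally.residual_weight


def test_step_modes_agree_without_absorption():
    """With mu_a = 0 the two step-length modes consume identical random
    streams, hence produce bitwise-identical results."""
    stack = single_layer_stack(mu_a=0.0, mu_s=20.0, g=0.8, n=1.4)
    out = {}
    for mode in ("paper-literal", "mcml-standard"):
        params = TransportParams(step_mode=mode, z_max_mm=20.0)
        out[mode] = run_photon_simulation(
            _pencil_source(), wide_detector(), stack, 5_000, 21, params
        ).tally
    a, b = out["paper-literal"], out["mcml-standard"]
    assert a.escaped_weight == b.escaped_weight
    assert a.n_detected == b.n_detected
    assert a.residual_weight == b.residual_weight


def test_paired_channels_with_identical_stacks_are_identical():
    stack = build_tissue_stack(PhysioState(0.9, 0.105), 850.0)
    src = SourceConfig("VCSEL_IR", 850.0)
    det = default_detector(3.0)
    params = TransportParams(step_mode="paper-literal")
    r1, r2 = run_paired_simulation(src, det, [stack, stack], 10_000, 5, params)
    assert r1.tally.detected_weight == r2.tally.detected_weight
    assert np.array_equal(r1.tally.absorbed_by_layer, r2.tally.absorbed_by_layer)


def test_paired_requires_shared_geometry():
    a = build_tissue_stack(PhysioState(0.9, 0.105), 850.0)
    b = build_tissue_stack(PhysioState(0.9, 0.105), 660.0)  # different mu_s/g
    src = SourceConfig("VCSEL_IR", 850.0)
    with pytest.raises(ValidationError):
        run_paired_simulation(
            src, default_detector(3.0), [a, b], 100, 0,
            TransportParams(step_mode="paper-literal"),
        )


def test_zero_packets_rejected():
    stack = build_tissue_stack(PhysioState(0.9, 0.105), 660.0)
    with pytest.raises(ValidationError):
        run_photon_simulation(
            SourceConfig("LED_R", 660.0), default_detector(3.0), stack, 0, 0
        )


def test_grazing_packets_counted_not_entering():
    """A broad profile tilted away from the detector sends some packets
    parallel/upward in air; they are rejected yet the audit still closes."""
    from oximc.beam_sources import normalize_and_cdf

    theta = np.linspace(0.0, math.radians(89.0), 200)
    broad = normalize_and_cdf(theta, np.ones_like(theta), profile_id="broad")
    src = SourceConfig("VCSEL_R", 660.0, tilt_deg=-45.0, custom_profile=broad)
    stack = build_tissue_stack(PhysioState(0.9, 0.105), 660.0)
    res = run_photon_simulation(src, default_detector(3.0), stack, 5_000, 13)
    assert res.tally.n_rejected > 0
    assert res.tally.audit_error() < 1e-6


def test_systole_detects_less_light_than_diastole(paired_red_run):
    res_dia, res_sys = paired_red_run
    assert res_dia.intensity > res_sys.intensity > 0
    pi = (res_dia.intensity - res_sys.intensity) / res_sys.intensity
    assert 0 < pi < 1


# -------------------------------------------------- detected-path absorption

def _tally(absorbed_det, n_detected=5):
    L = len(absorbed_det)
    return DetectionTally(
        n_launched=100,
        n_rejected=0,
        n_detected=n_detected,
        specular_weight=0.0,
        absorbed_by_layer=np.asarray(absorbed_det, dtype=float),
        absorbed_detected_by_layer=np.asarray(absorbed_det, dtype=float),
        escaped_weight=0.0,
        detected_weight=1.0,
        residual_weight=0.0,
        unscattered_terminal_weight=0.0,
        layer_names=tuple(["epidermis"] + [f"l{i}" for i in range(1, L)]),
    )


def test_epidermis_absorption_fraction_limits():
    assert epidermis_absorption_fraction(_tally([2.0, 0.0, 0.0])) == 1.0
    assert epidermis_absorption_fraction(_tally([0.0, 1.0, 3.0])) == 0.0
    assert epidermis_absorption_fraction(_tally([1.0, 1.0, 2.0])) == pytest.approx(0.25)
    with pytest.raises(ValidationError):
        epidermis_absorption_fraction(_tally([1.0, 1.0], n_detected=0))
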