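"""Jitter model: degraded retinotopy, Kendall's tau, sigma estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from retinotract import jitter, mc
from retinotract.jitter import (
    JitterConfig,
    compute_tau,
    estimate_retinotopy,
    simulate_jittered_pairs,
    sweep_sigma,
    tau_normal_approx,
)


def _disk_pair_distance_median(R, d_min=0.0):
    """Independent oracle: median separation of two uniform points in a
    disk of radius R, conditioned on separation > d_min (numerical
    integration of the known disk line-picking density)."""

    def pdf(s):
        x = s / (2 * R)
        return 4 * s / (np.pi * R**2) * (np.arccos(x) - x * np.sqrt(1 - x**2))

    norm = integrate.quad(pdf, d_min, 2 * R)[0]

    def cdf_minus_half(m):
        return integrate.quad(pdf, d_min, m)[0] / norm - 0.5

    from scipy.optimize import brentq

    return brentq(cdf_minus_half, d_min + 1e-9, 2 * R - 1e-9)


def test_zero_jitter_has_no_rejections_and_matches_disk_oracle():
    cfg = JitterConfig(seed=1)
    rng = np.random.default_rng(2)
    d, rej = simulate_jittered_pairs(0.0, cfg, rng, 40_000)
    assert rej == 0.0
    oracle = _disk_pair_distance_median(cfg.range_deg, cfg.exclusion_um * cfg.g_deg_per_um)
    assert np.median(d) == pytest.approx(oracle, rel=0.03)
    # the 2D disk geometry sits somewhat below the 3D ball-model median
    ball = mc.predict_rf_distance(mc.MCConfig.preset("ot", seed=3)).median_deg
    assert np.median(d) == pytest.approx(ball, rel=0.15)


def test_pair_separation_bounded_by_disk_diameter():
    cfg = JitterConfig(seed=4)
    rng = np.random.default_rng(4)
    d, _ = simulate_jittered_pairs(0.0, cfg, rng, 10_000)
    assert d.max() <= 2 * cfg.recording_range_um * cfg.g_deg_per_um + 1e-9  # 18 deg
    assert d.min() > cfg.exclusion_um * cfg.g_deg_per_um


def test_large_jitter_causes_rejections_and_inflates_distances():
    cfg = JitterConfig(seed=5)
    rng = np.random.default_rng(5)
    d0, rej0 = simulate_jittered_pairs(0.0, cfg, rng, 5_000)
    d5, rej5 = simulate_jittered_pairs(0.5, cfg, rng, 5_000)
    assert rej5 > 0
    assert np.median(d5) > np.median(d0)


def test_ball3d_geometry_flag():
    cfg = JitterConfig(seed=6, geometry="ball3d")
    rng = np.random.default_rng(6)
    d, rej = simulate_jittered_pairs(0.0, cfg, rng, 5_000)
    assert rej == 0.0
    # cross-sectional projection of a ball pair: bounded by the diameter
    assert d.max() <= 2 * cfg.recording_range_um * cfg.g_deg_per_um + 1e-9
    with pytest.raises(ValueError):
        JitterConfig(geometry="cube")


def test_tau_is_one_at_zero_jitter_exactly():
    cfg = JitterConfig(seed=7, tau_axons=200, tau_repeats=2)
    assert compute_tau(0.0, cfg, np.random.default_rng(0)) == 1.0


def test_tau_vanishes_for_noise_dominated_maps():
    cfg = JitterConfig(seed=8, tau_axons=600, tau_repeats=10)
    tau = compute_tau(10.0, cfg, np.random.default_rng(8))
    assert abs(tau) < 0.05


def test_tau_against_bivariate_normal_approximation():
    """Greiner's relation tau = (2/pi) asin(rho) predicts the simulated
    tau closely; at sigma = 0.13 both sit near 0.49."""
    cfg = JitterConfig(seed=9, tau_axons=2_000, tau_repeats=10)
    rng = np.random.default_rng(9)
    for sigma in (0.05, 0.13, 0.3):
        sim = compute_tau(sigma, cfg, rng)
        assert sim == pytest.approx(tau_normal_approx(sigma, cfg), abs=0.03)
    assert tau_normal_approx(0.13, cfg) == pytest.approx(0.49, abs=0.03)


def test_sweep_grid_and_monotonicity(default_sweep):
    cfg, curve = default_sweep
    assert len(curve) == 11  # sigma = 0 to 0.5 in steps of 0.05
    assert curve["tau"].iloc[0] == 1.0
    # tau non-increasing, medians non-decreasing (Monte Carlo slack)
    assert (np.diff(curve["tau"]) <= 0.02).all()
    assert (np.diff(curve["median_deg"]) >= -0.3).all()
    med = dict(zip(curve["sigma"], curve["median_deg"]))
    assert med[0.25] > med[0.05]
    assert (curve["q25_deg"] <= curve["median_deg"]).all()
    assert (curve["median_deg"] <= curve["q75_deg"]).all()


def test_empty_grid_rejected():
    with pytest.raises(ValueError):
        sweep_sigma(JitterConfig(sigma_grid=[], seed=0))
    with pytest.raises(ValueError):
        JitterConfig(sigma_grid=[-0.1])


def test_estimate_at_curve_left_endpoint(default_sweep):
    cfg, curve = default_sweep
    est = estimate_retinotopy(float(curve["median_deg"].iloc[0]), curve, cfg)
    assert est.sigma_star == 0.0
    assert est.tau_star == 1.0


def test_estimate_out_of_range_raises(default_sweep):
    cfg, curve = default_sweep
    with pytest.raises(ValueError, match="outside the simulated range"):
        estimate_retinotopy(1.0, curve, cfg)
    with pytest.raises(ValueError, match="outside the simulated range"):
        estimate_retinotopy(500.0, curve, cfg)


@pytest.mark.parametrize("sigma_star", [0.07, 0.13, 0.31])
def test_unit_conversions_are_exact_identities(sigma_star):
    curve = pd.DataFrame(
        dict(
            sigma=[0.0, 0.5],
            median_deg=[5.0, 30.0],
            tau=[1.0, 0.2],
        )
    )
    cfg = JitterConfig(seed=0)
    measured = float(np.interp(sigma_star, curve["sigma"], curve["median_deg"]))
    est = estimate_retinotopy(measured, curve, cfg)
    assert est.deviation_deg / cfg.field_span_deg == pytest.approx(est.sigma_star)
    assert est.displacement_um / cfg.tract_width_um == pytest.approx(est.sigma_star)


def test_sweep_is_seed_reproducible():
    cfg = JitterConfig(seed=55, trials_per_sigma=2_000, tau_axons=200,
                       tau_repeats=3, sigma_grid=[0.0, 0.1, 0.2])
    a = sweep_sigma(cfg)
    b = sweep_sigma(JitterConfig(seed=55, trials_per_sigma=2_000, tau_axons=200,
                                 tau_repeats=3, sigma_grid=[0.0, 0.1, 0.2]))
    pd.testing.assert_frame_equal(a, b)
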