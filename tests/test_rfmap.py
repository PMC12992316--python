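"""Reverse-correlation RF mapping: STA, null calibration, SVD, fits."""

import numpy as np
import pytest
from scipy import stats

from retinotract import rfmap, stimulus
from retinotract.rfmap import (
    STAResult,
    compute_sta,
    fit_rf_gaussian,
    map_unit,
    separate_rf,
    sta_pvalues,
)


def _null_sta(stim, n_spikes, seed):
    """STA of spikes placed on distinct random frames, independent of the
    stimulus — the N(0, 1/C) null regime."""
    rng = np.random.default_rng(seed)
    frames = rng.choice(
        np.arange(29, stim.n_frames), size=n_spikes, replace=False
    )
    t = np.sort(frames * stim.dt_s + 0.5 * stim.dt_s)
    return compute_sta(t, stim)


def test_single_spike_sta_is_the_preceding_stimulus_segment(small_stim):
    f = 123
    t = np.array([f * small_stim.dt_s + 0.002])
    sta = compute_sta(t, small_stim)
    assert sta.spike_count == 1
    for lag in range(sta.n_lags):
        np.testing.assert_array_equal(sta.sta[lag], small_stim.frames[f - lag])


def test_half_second_window_gives_30_lags(small_stim):
    sta = _null_sta(small_stim, 50, 0)
    assert sta.n_lags == 30
    assert sta.window_s == 0.5
    assert sta.dt_s == pytest.approx(1 / 60)


def test_early_spikes_excluded_and_empty_average_raises(small_stim):
    # a spike before the window has no complete history
    with pytest.raises(ValueError):
        compute_sta(np.array([0.05]), small_stim)
    sta = compute_sta(np.array([0.05, 200 * small_stim.dt_s]), small_stim)
    assert sta.spike_count == 1


def test_null_sta_voxels_follow_normal_null():
    stim = stimulus.generate_checkerboard(9_000, seed=31)
    sta = _null_sta(stim, 400, seed=32)
    z = (sta.sta * np.sqrt(sta.spike_count)).ravel()
    # KS on a subsample where the +-1-sum lattice (step 2/sqrt(C) in z
    # units) stays below the test's critical value
    sub = np.random.default_rng(33).choice(z, size=500, replace=False)
    assert stats.kstest(sub, "norm").pvalue > 0.01


@pytest.mark.parametrize("alpha", [1e-2, 1e-3])
def test_null_pvalue_calibration(alpha):
    """Fraction of voxels below alpha matches the exact discrete null."""
    stim = stimulus.generate_checkerboard(30_000, seed=41)
    sta = _null_sta(stim, 2_000, seed=42)
    p = sta_pvalues(sta)
    C = sta.spike_count
    # exact tail of the +-1 sum: |2K - C| > z * sqrt(C), K ~ Binom(C, 1/2)
    zcrit = stats.norm.isf(alpha / 2) * np.sqrt(C)
    k_hi = int(np.floor((C + zcrit) / 2))
    q = 2 * stats.binom.sf(k_hi, C, 0.5)
    frac = (p < alpha).mean()
    se = np.sqrt(q * (1 - q) / p.size)
    assert abs(frac - q) < 4 * se + 0.1 * q


def test_pvalue_examples():
    sta = STAResult(sta=np.zeros((30, 18, 32)), spike_count=100)
    assert sta_pvalues(sta).max() == 1.0
    sta.sta[0, 0, 0] = 0.5  # z = 0.5 * sqrt(100) = 5
    p = sta_pvalues(sta)[0, 0, 0]
    assert p == pytest.approx(2 * stats.norm.sf(5.0), rel=1e-9)
    assert p == pytest.approx(5.7e-7, rel=0.01)


def test_svd_recovers_exact_outer_product():
    k = np.zeros(30)
    k[3], k[8] = 1.0, -0.4
    k /= np.linalg.norm(k)
    spatial_true = np.zeros((18, 32))
    spatial_true[9, 16] = 2.0
    spatial_true[9, 17] = 1.0
    sta = STAResult(sta=k[:, None, None] * spatial_true[None], spike_count=100)
    spatial, temporal = separate_rf(sta)
    np.testing.assert_allclose(temporal, k, atol=1e-12)
    np.testing.assert_allclose(spatial, spatial_true, atol=1e-12)


def test_svd_sign_convention_for_off_unit():
    k = np.zeros(30)
    k[3], k[8] = 1.0, -0.4  # positive temporal peak
    k /= np.linalg.norm(k)
    spatial_true = np.zeros((18, 32))
    spatial_true[5, 5] = -3.0  # OFF: negative spatial extremum
    sta = STAResult(sta=k[:, None, None] * spatial_true[None], spike_count=100)
    spatial, temporal = separate_rf(sta)
    assert spatial[5, 5] < 0
    assert temporal[np.abs(temporal).argmax()] > 0


def test_rank1_reconstruction_error_bounded_by_residual_energy():
    rng = np.random.default_rng(9)
    mat = rng.standard_normal((30, 18 * 32)) * 0.05
    sta = STAResult(sta=mat.reshape(30, 18, 32), spike_count=500)
    spatial, temporal = separate_rf(sta)
    recon = temporal[:, None] * spatial.reshape(1, -1)
    resid = np.linalg.norm(mat - recon) ** 2
    svals = np.linalg.svd(mat, compute_uv=False)
    assert resid <= (svals[1:] ** 2).sum() + 1e-9


def test_degenerate_sta_raises():
    sta = STAResult(sta=np.zeros((30, 18, 32)), spike_count=10)
    with pytest.raises(ValueError):
        separate_rf(sta)


def test_gaussian_fit_on_noiseless_image(small_stim):
    az, el = small_stim.pixel_centers_deg()
    AZ, EL = np.meshgrid(az, el)
    img = 1.5 * np.exp(-0.5 * (((AZ - 4.0) / 2.0) ** 2 + ((EL + 3.0) / 1.0) ** 2))
    center, sigma, theta, amp, off, ok = fit_rf_gaussian(img, small_stim)
    assert ok
    assert center[0] == pytest.approx(4.0, abs=0.05)
    assert center[1] == pytest.approx(-3.0, abs=0.05)
    # size = mean of 1-sigma diameters = (2*2 + 2*1)/2 = 3 deg
    assert sigma[0] + sigma[1] == pytest.approx(3.0, abs=0.1)
    assert sigma[0] >= sigma[1] > 0


def test_latency_definition():
    # temporal extremum at lag 3 with dt = 1/60 s -> 50 ms
    k = np.zeros(30)
    k[3] = -1.0
    spatial = np.zeros((18, 32))
    spatial[4, 4] = -1.0
    fit = rfmap.classify_unit(
        k, spatial, (0.0, 0.0), (1.0, 1.0), 0.0, -1.0, 0.0, True,
        1e-9, True, "OT",
    )
    assert fit.peak_latency_ms == pytest.approx(50.0)
    assert fit.polarity == -1  # negative extremum -> OFF
    assert fit.passed_qc


def test_size_threshold_excludes_wide_field_units_in_ot_mode():
    k = np.zeros(30)
    k[3] = 1.0
    spatial = np.zeros((18, 32))
    spatial[4, 4] = 1.0
    big = rfmap.classify_unit(
        k, spatial, (0.0, 0.0), (9.0, 8.0), 0.0, 1.0, 0.0, True,
        1e-9, True, "OT",
    )
    assert big.size_deg == 17.0 and not big.passed_qc
    lgn = rfmap.classify_unit(
        k, spatial, (0.0, 0.0), (9.0, 8.0), 0.0, 1.0, 0.0, True,
        1e-9, True, "LGN",
    )
    assert lgn.passed_qc  # threshold applies to OT only


def test_size_definition_recomputable_from_sigmas():
    fit = rfmap.RFFit(
        center_deg=(0, 0), sigma_deg=(2.5, 1.5), orientation_rad=0.0,
        amplitude=1.0, offset=0.0, polarity=1, peak_latency_ms=50.0,
        min_p=1e-9, fit_converged=True, localized=True, passed_qc=True,
    )
    assert fit.size_deg == (2 * 2.5 + 2 * 1.5) / 2


def test_parameter_recovery_on_simulated_units(recovery_cohort):
    """Center, size, polarity and latency recovered from LN simulations."""
    stim, pop, spk = recovery_cohort
    pix = float(np.mean(stim.pixel_size_deg))
    center_err, size_err, lat_err, pol_ok = [], [], [], []
    for i in range(pop.n_units):
        assert len(spk.spike_times_s[i]) >= 1_000
        fit = map_unit(spk.spike_times_s[i], stim, mode="OT")
        center_err.append(
            np.hypot(
                fit.center_deg[0] - pop.rf_center_deg[i, 0],
                fit.center_deg[1] - pop.rf_center_deg[i, 1],
            ) / pix
        )
        size_err.append(
            abs(fit.size_deg - pop.rf_size_deg[i]) / pop.rf_size_deg[i]
        )
        true_lat = np.abs(pop.temporal_kernel[i]).argmax() / 60 * 1000
        lat_err.append(abs(fit.peak_latency_ms - true_lat))
        pol_ok.append(fit.polarity == pop.polarity[i])
    assert np.median(center_err) < 0.5
    assert np.median(size_err) < 0.20
    assert all(pol_ok)
    assert np.median(lat_err) <= 1000 / 60 + 1e-9


def test_sta_is_deterministic(recovery_cohort):
    stim, pop, spk = recovery_cohort
    a = compute_sta(spk.spike_times_s[0], stim).sta
    b = compute_sta(spk.spike_times_s[0], stim).sta
    np.testing.assert_array_equal(a, b)
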