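import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcrepro.adc_fitting import (
    NONPHYSICAL,
    PRESPECIFIED_CONDITIONS,
    BValueSet,
    CalcCondition,
    FitOptions,
    Mode,
    Statistic,
    aggregate_map,
    compute_condition_adc,
    fit_voxel_map,
    log_linear_fit,
    roi_signal_fit,
    weighted_log_linear_fit,
)
from adcrepro.dwi_data import DWISeries, ROIMask
from adcrepro.synthetic_data import PhantomTissue, add_rician_noise, ivim_signal
from conftest import box_mask, homogeneous_series

B5 = np.array([0.0, 30.0, 80.0, 150.0, 500.0])


def oracle_wls(b, y, w):
    """Independent closed-form weighted regression via normal equations."""
    X = np.column_stack([np.ones_like(b), b])
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta  # (intercept, slope)


def test_two_point_fit_is_exact_interpolation():
    res = log_linear_fit([150, 500], [100 * np.exp(-0.15), 100 * np.exp(-0.5)])
    assert res.adc == pytest.approx(1.0e-3, rel=1e-12)
    assert res.s0 == pytest.approx(100.0, rel=1e-12)
    assert res.r_squared is None and res.n_points == 2


def test_constant_signal_gives_zero_adc():
    res = log_linear_fit([0, 150, 500], [100.0, 100.0, 100.0])
    assert res.adc == pytest.approx(0.0, abs=1e-15)
    assert res.s0 == pytest.approx(100.0)
    assert res.r_squared == pytest.approx(1.0)  # zero-residual degenerate fit


@pytest.mark.parametrize("method,fitter", [("lls", log_linear_fit), ("wlls", weighted_log_linear_fit)])
def test_fits_match_normal_equation_oracle(method, fitter):
    s0, adc = 200.0, 1.4e-3
    perturb = np.array([0.98, 1.01, 1.00, 1.02, 0.97])
    S = s0 * np.exp(-B5 * adc) * perturb
    y = np.log(S)
    w = S**2 if method == "wlls" else np.ones_like(S)
    intercept, slope = oracle_wls(B5, y, w)
    res = fitter(B5, S)
    assert res.adc == pytest.approx(-slope, rel=1e-12)
    assert res.s0 == pytest.approx(np.exp(intercept), rel=1e-12)
    assert res.n_points == 5 and 0 <= res.r_squared <= 1


def test_lls_and_wlls_agree_on_two_points_and_exact_data():
    # 2-point fits interpolate perfectly regardless of weights
    for S in ([80.0, 20.0], [5.0, 400.0]):
        a = log_linear_fit([150, 500], S)
        b = weighted_log_linear_fit([150, 500], S)
        assert a.adc == pytest.approx(b.adc, rel=1e-12)
    # exact exponential: zero residual, weights irrelevant
    S = 150.0 * np.exp(-B5 * 0.9e-3)
    a, b = log_linear_fit(B5, S), weighted_log_linear_fit(B5, S)
    assert a.adc == pytest.approx(b.adc, rel=1e-10)
    assert a.adc == pytest.approx(0.9e-3, rel=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    k=st.floats(1e-3, 1e3),
    adc=st.floats(1e-4, 3e-3),
    method=st.sampled_from(["lls", "wlls"]),
)
def test_scale_invariance(k, adc, method):
    S = 100.0 * np.exp(-B5 * adc) * np.array([1.02, 0.99, 1.0, 0.98, 1.01])
    fitter = log_linear_fit if method == "lls" else weighted_log_linear_fit
    base, scaled = fitter(B5, S), fitter(B5, k * S)
    assert scaled.adc == pytest.approx(base.adc, rel=1e-9)
    assert scaled.s0 == pytest.approx(k * base.s0, rel=1e-9)


def test_nonpositive_signal_policies():
    S = np.array([100.0, 85.0, 0.0, 60.0, 30.0])
    res = log_linear_fit(B5, S, FitOptions(nonpositive_policy="drop_point"))
    assert res.n_points == 4
    with pytest.raises(ValueError, match="usable"):
        log_linear_fit(B5, S, FitOptions(nonpositive_policy="drop_voxel"))
    with pytest.raises(ValueError, match="usable"):
        log_linear_fit(B5, np.zeros(5))
    with pytest.raises(ValueError, match="min_points"):
        FitOptions(min_points=1)


def test_voxel_map_homogeneous_noiseless():
    series = homogeneous_series(adc=1.0e-3)
    mask = box_mask(series.spatial_shape, (0, 0, 0), (6, 6, 4), spacing=series.spacing)
    amap = fit_voxel_map(series, mask)
    assert amap.n_excluded == 0 and amap.n_used == mask.n_voxels
    np.testing.assert_allclose(amap.retained_values(), 1.0e-3, rtol=1e-10)


def test_voxel_map_flags_nonphysical_and_conserves_counts():
    series = homogeneous_series(adc=1.0e-3)
    sig = series.signal.copy()
    sig[0, 0, 0, :] = 50.0 * np.exp(+B5 * 0.5e-3)  # rising with b -> adc < 0
    series = DWISeries(signal=sig, b_values=series.b_values, spacing=series.spacing)
    mask = box_mask(series.spatial_shape, (0, 0, 0), (6, 6, 4), spacing=series.spacing)
    amap = fit_voxel_map(series, mask, FitOptions(physical_range=(0.0, 4.0e-3)))
    flagged = [e for e in amap.excluded if e is not None]
    assert flagged == [NONPHYSICAL]
    assert amap.n_used + amap.n_excluded == mask.n_voxels


def test_voxel_map_matches_per_voxel_oracle(rng):
    tissue = PhantomTissue(s0=100.0, d=1.2e-3, f=0.0)
    shape = (10, 10, 10)  # 1000 voxels
    signal = np.broadcast_to(ivim_signal(B5, tissue), shape + (5,)).copy()
    series = add_rician_noise(
        DWISeries(signal, B5, (1.0, 1.0, 1.0)), sigma=2.0, seed=42
    )
    mask = box_mask(shape, (0, 0, 0), shape)
    amap = fit_voxel_map(series, mask, FitOptions("lls", physical_range=(-1.0, 1.0)))
    # oracle: per-voxel polyfit loop, same filter applied afterwards
    oracle = []
    for v in series.signal[mask.mask]:
        slope, intercept = np.polyfit(B5, np.log(v), 1)
        if -1.0 <= -slope <= 1.0:
            oracle.append(-slope)
    assert amap.n_used == len(oracle)
    assert np.mean(amap.retained_values()) == pytest.approx(np.mean(oracle), rel=1e-9)


def test_roi_signal_fit_hand_example():
    # 2 voxels, b=(0,500): signals (100,50) and (60,10); mean = (75, 35)
    signal = np.zeros((2, 1, 1, 2))
    signal[0, 0, 0] = [100.0, 60.0]
    signal[1, 0, 0] = [50.0, 10.0]
    series = DWISeries(signal, [0.0, 500.0], (1.0, 1.0, 1.0))
    mask = box_mask((2, 1, 1), (0, 0, 0), (2, 1, 1))
    res = roi_signal_fit(series, mask, Statistic.MEAN)
    assert res.adc == pytest.approx(np.log(75 / 35) / 500, rel=1e-12)
    # median of two voxels equals their mean
    res_med = roi_signal_fit(series, mask, Statistic.MEDIAN)
    assert res_med.adc == pytest.approx(res.adc, rel=1e-12)


def test_roi_fit_equals_voxel_fit_for_homogeneous_roi():
    series = homogeneous_series(adc=1.3e-3)
    mask = box_mask(series.spatial_shape, (1, 1, 1), (4, 4, 3), spacing=series.spacing)
    roi = roi_signal_fit(series, mask, Statistic.MEAN)
    amap = fit_voxel_map(series, mask)
    assert roi.adc == pytest.approx(amap.retained_values()[0], rel=1e-10)


def test_aggregate_map_statistics_and_filtering():
    idx = np.argwhere(np.ones((3, 1, 1), bool))
    amap_args = dict(shape=(3, 1, 1), indices=idx)
    from adcrepro.adc_fitting import ADCMap

    amap = ADCMap(
        values=np.array([1e-3, 2e-3, 3e-3]),
        excluded=np.array([None, None, None], dtype=object),
        **amap_args,
    )
    assert aggregate_map(amap, Statistic.MEAN) == pytest.approx(2e-3)
    amap_skew = ADCMap(
        values=np.array([1e-3, 2e-3, 10e-3]),
        excluded=np.array([None, None, None], dtype=object),
        **amap_args,
    )
    assert aggregate_map(amap_skew, Statistic.MEDIAN) == pytest.approx(2e-3)
    # excluded voxels do not contribute
    half = ADCMap(
        values=np.array([1e-3, 2e-3, 9e-3]),
        excluded=np.array([None, None, NONPHYSICAL], dtype=object),
        **amap_args,
    )
    assert aggregate_map(half, Statistic.MEAN) == pytest.approx(1.5e-3)
    all_out = ADCMap(
        values=np.array([np.nan] * 3),
        excluded=np.array([NONPHYSICAL] * 3, dtype=object),
        **amap_args,
    )
    with pytest.raises(ValueError, match="retained"):
        aggregate_map(all_out)


def test_condition_dispatch_noiseless_recovery():
    truth = 1.0e-3
    series = homogeneous_series(adc=truth)
    mask = box_mask(series.spatial_shape, (0, 0, 0), (5, 5, 3), spacing=series.spacing)
    for cond in PRESPECIFIED_CONDITIONS:
        for method in ("lls", "wlls"):
            adc = compute_condition_adc(series, mask, cond, FitOptions(method))
            assert adc == pytest.approx(truth, rel=1e-10), cond.label


def test_perfusion_inflates_all_b_condition():
    tissue = PhantomTissue(s0=100.0, d=1.0e-3, f=0.1, d_star=50e-3)
    shape = (5, 5, 3)
    signal = np.broadcast_to(ivim_signal(B5, tissue), shape + (5,)).copy()
    series = DWISeries(signal, B5, (2.0, 2.0, 4.0))
    mask = box_mask(shape, (0, 0, 0), shape, spacing=series.spacing)
    all_b = compute_condition_adc(
        series, mask, CalcCondition(BValueSet.ALL, Mode.VOXEL_BASED, Statistic.MEDIAN)
    )
    high_b = compute_condition_adc(
        series, mask, CalcCondition(BValueSet.B_GE_150, Mode.VOXEL_BASED, Statistic.MEDIAN)
    )
    assert all_b > high_b


def test_condition_b150_roi_mean_closed_form():
    signal = np.zeros((2, 1, 1, 5))
    signal[0, 0, 0] = [130.0, 120.0, 110.0, 100.0, 60.0]
    signal[1, 0, 0] = [80.0, 70.0, 65.0, 50.0, 10.0]
    series = DWISeries(signal, B5, (1.0, 1.0, 1.0))
    mask = box_mask((2, 1, 1), (0, 0, 0), (2, 1, 1))
    adc = compute_condition_adc(
        series, mask, CalcCondition(BValueSet.B_GE_150, Mode.ROI_BASED, Statistic.MEAN)
    )
    # aggregated signals at b=150,500 are (75, 35): 2-point closed form
    assert adc == pytest.approx(np.log(75 / 35) / 350, rel=1e-12)


def test_wlls_is_more_efficient_than_lls_under_additive_noise(rng):
    s0, adc, sigma, n_rep = 100.0, 1.0e-3, 2.0, 2000  # sigma = s0/50
    clean = s0 * np.exp(-B5 * adc)
    noisy = np.clip(clean + rng.normal(0, sigma, (n_rep, 5)), 1e-6, None)
    adcs = {"lls": [], "wlls": []}
    for row in noisy:
        adcs["lls"].append(log_linear_fit(B5, row).adc)
        adcs["wlls"].append(weighted_log_linear_fit(B5, row).adc)
    assert np.var(adcs["wlls"]) <= 1.1 * np.var(adcs["lls"])


def test_noise_floor_biases_adc_downward(rng):
    # SNR at b=500 <= 3: the Rician floor props up high-b signal -> ADC under-read
    truth, s0 = 1.5e-3, 100.0
    snr500 = s0 * np.exp(-500 * truth) / 20.0
    assert snr500 <= 3
    shape = (12, 12, 8)  # 1152 voxels
    signal = np.broadcast_to(s0 * np.exp(-B5 * truth), shape + (5,)).copy()
    series = add_rician_noise(DWISeries(signal, B5, (1, 1, 1)), sigma=20.0, seed=3)
    mask = box_mask(shape, (0, 0, 0), shape)
    amap = fit_voxel_map(series, mask, FitOptions("lls", physical_range=(-10.0, 10.0)))
    assert np.median(amap.retained_values()) < truth


def test_prespecified_grid_has_eight_distinct_conditions():
    assert len(PRESPECIFIED_CONDITIONS) == 8
    assert len({c.label for c in PRESPECIFIED_CONDITIONS}) == 8
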