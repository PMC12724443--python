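"""Response strength, thresholds, peaks, latency shifts, correlations,
threshold shifts, and the averaging noise-floor law."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from abrkit.metrics import (
    MetricConfig,
    ThresholdEstimate,
    estimate_threshold,
    find_primary_peak,
    latency_shift,
    noise_floor_curve,
    rolling_strength,
    threshold_shift,
    waveform_correlation,
)
from abrkit.synthesize import SynthConfig, _gabor, _response_templates, band_noise_trials

FS = 16000.0
CFG = MetricConfig()


# ---------------------------------------------------------------------------
# Rolling strength


def test_constant_waveform_has_zero_strength():
    s = rolling_strength(np.full(160, 3.3), FS)
    assert np.nanmax(s) < 1e-12
    assert np.isnan(s[0]) and np.isnan(s[-1])  # edges undefined


def test_strength_of_unit_step():
    # a window straddling a unit step half-and-half has SD 0.5*sqrt(n/(n-1))
    x = np.zeros(160)
    x[80:] = 1.0
    s = rolling_strength(x, FS)
    n = 20
    assert np.nanmax(s) == pytest.approx(0.5 * np.sqrt(n / (n - 1)), rel=1e-9)


def test_white_noise_strength_converges_to_sigma():
    rng = np.random.default_rng(0)
    s = rolling_strength(rng.normal(scale=2.0, size=200_000), FS)
    assert np.nanmean(s) == pytest.approx(2.0, rel=0.05)


@given(st.floats(-1e-3, 1e-3), st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3))
def test_strength_offset_invariant_and_scale_equivariant(offset, scale):
    rng = np.random.default_rng(42)
    x = rng.normal(size=160)
    base = rolling_strength(x, FS)
    shifted = rolling_strength(x + offset, FS)
    scaled = rolling_strength(scale * x, FS)
    np.testing.assert_allclose(shifted, base, atol=1e-12)
    np.testing.assert_allclose(scaled, np.abs(scale) * base, rtol=1e-9)


def test_window_longer_than_waveform_rejected():
    with pytest.raises(ValueError, match="longer"):
        rolling_strength(np.zeros(10), FS)


# ---------------------------------------------------------------------------
# Threshold estimation


def test_threshold_interpolates_between_levels():
    est = estimate_threshold([33.0, 37.0], [0.25e-6, 0.35e-6])
    assert est.threshold_db == pytest.approx(35.0)
    assert est.censoring == "none"
    assert (est.level_below, est.level_above) == (33.0, 37.0)


def test_threshold_at_exact_criterion_level():
    est = estimate_threshold([33.0, 37.0], [0.2e-6, 0.3e-6])
    assert est.threshold_db == pytest.approx(37.0)


def test_threshold_censoring():
    levels = np.arange(25.0, 74.0, 4.0)
    low = estimate_threshold(levels, np.full(13, 1e-6))
    assert low.censoring == "below_grid" and low.threshold_db == 25.0
    high = estimate_threshold(levels, np.full(13, 0.1e-6))
    assert high.censoring == "above_grid" and high.threshold_db == 73.0
    with pytest.raises(ValueError):
        estimate_threshold([33.0], [1e-6])


def test_highest_crossing_wins_over_spurious_bump():
    levels = [25.0, 29.0, 33.0, 37.0]
    strengths = [0.4e-6, 0.1e-6, 0.2e-6, 0.5e-6]  # spurious bump at 25
    est = estimate_threshold(levels, strengths)
    assert 33.0 < est.threshold_db < 37.0


@given(st.lists(st.floats(0.01, 1.0), min_size=5, max_size=13), st.integers(0, 2**31 - 1))
def test_raising_strengths_cannot_raise_threshold(strengths_uv, seed):
    levels = 25.0 + 4.0 * np.arange(len(strengths_uv))
    s = np.asarray(strengths_uv) * 1e-6
    rng = np.random.default_rng(seed)
    s_up = s + rng.uniform(0, 0.5e-6, size=s.size)
    t0 = estimate_threshold(levels, s).threshold_db
    t1 = estimate_threshold(levels, s_up).threshold_db
    assert t1 <= t0 + 1e-9


def test_log_space_interpolation_option():
    est = estimate_threshold([33.0, 37.0], [0.15e-6, 0.6e-6], space="log")
    assert 33.0 < est.threshold_db < 37.0


# ---------------------------------------------------------------------------
# Primary peak


def _epoch_time():
    return (np.arange(160) - 40) / FS


def test_primary_peak_recovered_from_synthetic_kernel():
    t = _epoch_time()
    wave = 3e-6 * _gabor(t, 1.40e-3, 1.0e-3, 0.5e-3)
    pk = find_primary_peak(wave, t)
    assert pk.found
    assert pk.latency == pytest.approx(1.40e-3, abs=0.02e-3)
    assert pk.amplitude == pytest.approx(-3e-6, rel=0.02)


def test_positive_only_deflection_has_no_primary_peak():
    # a purely positive bump offers no negative extremum to report
    t = _epoch_time()
    wave = 3e-6 * np.exp(-((t - 1.4e-3) ** 2) / (2 * (0.5e-3) ** 2))
    assert not find_primary_peak(wave, t).found


def test_monotone_waveform_has_no_peak():
    t = _epoch_time()
    assert not find_primary_peak(np.linspace(0, -1e-6, 160), t).found


def test_peak_latency_robust_to_mild_noise():
    t = _epoch_time()
    rng = np.random.default_rng(3)
    errs = []
    for _ in range(20):
        wave = 3e-6 * _gabor(t, 1.40e-3, 1.0e-3, 0.5e-3) + rng.normal(scale=0.1e-6, size=160)
        pk = find_primary_peak(wave, t)
        errs.append(abs(pk.latency - 1.40e-3))
    assert max(errs) < 1 / FS  # within one sample


# ---------------------------------------------------------------------------
# Latency shift


def test_identical_waveforms_have_zero_slope():
    wave = _gabor(_epoch_time(), 1.4e-3, 1e-3, 0.5e-3)
    waves = np.tile(wave, (5, 1))
    fit = latency_shift(waves, np.array([57.0, 61.0, 65.0, 69.0, 73.0]), FS)
    assert fit.slope == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(fit.lags, 0.0, atol=1e-9)


def test_integer_sample_shift_measured_exactly():
    t = _epoch_time()
    ref = _gabor(t, 1.4e-3, 1e-3, 0.5e-3)
    shifted = np.roll(ref, 2)  # 2 samples = 125 us delay
    waves = np.vstack([ref, ref, shifted])
    fit = latency_shift(waves, np.array([73.0, 69.0, 65.0]), FS)
    lag_65 = fit.lags[list(fit.levels_db).index(65.0)]
    assert lag_65 == pytest.approx(125e-6, abs=5e-6)


def test_generator_latency_slope_recovered_from_templates():
    cfg = SynthConfig(kernel=SynthConfig().kernel)
    ips, _ = _response_templates(cfg)
    levels = np.array(sorted(ips), dtype=float)
    waves = np.stack([np.pad(ips[int(l)], (40, 160 - 40 - ips[int(l)].size)) for l in levels])
    fit = latency_shift(waves, levels, FS)
    assert fit.slope * 1e6 == pytest.approx(6.9, abs=0.8)


# ---------------------------------------------------------------------------
# Correlations


def test_waveform_correlation_extremes():
    rng = np.random.default_rng(0)
    w = rng.normal(size=(3, 160))
    same = waveform_correlation(w, w)
    np.testing.assert_allclose(np.diag(same.matrix), 1.0, atol=1e-12)
    flipped = waveform_correlation(w, -w)
    np.testing.assert_allclose(np.diag(flipped.matrix), -1.0, atol=1e-12)
    assert same.within_mean == pytest.approx(1.0)


def test_zero_variance_waveform_flagged():
    w = np.vstack([np.zeros(50), np.random.default_rng(1).normal(size=50)])
    summary = waveform_correlation(w, w)
    assert (0, 0) in summary.undefined
    assert np.isnan(summary.matrix[0, 0])


# ---------------------------------------------------------------------------
# Threshold shift


def _est(x, censoring="none"):
    return ThresholdEstimate(x, censoring)


def test_identical_thresholds_give_zero_shift():
    pre = {"m1": [_est(34.0), _est(36.0)], "m2": [_est(33.0)]}
    shift = threshold_shift(pre, pre)
    assert shift.mean == pytest.approx(0.0)


def test_shift_recovers_known_elevation():
    pre = {"m1": [_est(34.0)], "m2": [_est(36.0)], "m3": [_est(35.0)]}
    post = {"m1": [_est(59.0)], "m2": [_est(61.5)], "m3": [_est(60.0)]}
    shift = threshold_shift(pre, post)
    assert shift.mean == pytest.approx(25.17, abs=0.01)
    assert not shift.lower_bound_subjects


def test_censored_post_threshold_is_lower_bound():
    pre = {"m1": [_est(34.0)]}
    post = {"m1": [_est(73.0, "above_grid")]}
    shift = threshold_shift(pre, post)
    assert shift.per_subject["m1"] == pytest.approx(39.0)
    assert shift.lower_bound_subjects == ["m1"]


def test_mismatched_subjects_rejected():
    with pytest.raises(ValueError, match="differ"):
        threshold_shift({"m1": [_est(34.0)]}, {"m2": [_est(34.0)]})


# ---------------------------------------------------------------------------
# Noise floor


def test_noise_floor_slope_is_minus_half_for_independent_trials():
    trials = band_noise_trials(300, rms=1.5e-6, seed=5)
    curve = noise_floor_curve(trials, _epoch_time(), n_repeats=64, seed=0)
    assert curve.slope == pytest.approx(-0.5, abs=0.05)
    # sigma / sqrt(n): 1.5 uV over 64 trials -> ~0.19 uV
    i64 = list(curve.n_trials).index(64)
    assert curve.rms[i64] == pytest.approx(1.5e-6 / 8, rel=0.2)


def test_noise_floor_flat_for_identical_trials():
    trials = np.tile(np.random.default_rng(2).normal(size=160), (64, 1))
    curve = noise_floor_curve(trials, _epoch_time(), n_repeats=8, seed=0)
    assert curve.slope == pytest.approx(0.0, abs=1e-9)


def test_noise_floor_grid_truncated_with_warning():
    trials = band_noise_trials(20, seed=1)
    with pytest.warns(UserWarning, match="truncated"):
        curve = noise_floor_curve(trials, _epoch_time(), n_repeats=4, seed=0)
    assert curve.n_trials.max() <= 20
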