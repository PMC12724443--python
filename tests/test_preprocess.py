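"""Filtering, ECG detection, epoching, outlier rejection, and averaging."""

import warnings

import numpy as np
import pytest

from conftest import noiseless_config

from abrkit.acoustics import StimulusTrain
from abrkit.preprocess import (
    PipelineConfig,
    RawRecording,
    TrialTensor,
    average_by_level,
    bandpass,
    bandpass_recording,
    baseline_rms,
    detect_ecg,
    epoch,
    pool_average,
    reject_outliers,
)
from abrkit.synthesize import (
    AbrKernelSpec,
    EcgSpec,
    SynthConfig,
    band_noise_trials,
    generate_session,
    inject_outlier_trials,
)

FS = 16000.0


# ---------------------------------------------------------------------------
# Filtering


def test_bandpass_preserves_midband_and_rejects_out_of_band():
    t = np.arange(int(2 * FS)) / FS
    mid = np.sin(2 * np.pi * 1000.0 * t)
    out = bandpass(mid, FS, 300.0, 3000.0)[2000:-2000]
    assert np.max(np.abs(out)) == pytest.approx(1.0, rel=0.05)

    line = np.sin(2 * np.pi * 60.0 * t)
    attenuation = np.max(np.abs(bandpass(line, FS, 300.0, 3000.0)[2000:-2000]))
    assert attenuation < 10 ** (-20 / 20)  # at least 20 dB down

    dc = np.ones_like(t)
    assert np.max(np.abs(bandpass(dc, FS, 300.0, 3000.0)[2000:-2000])) < 1e-6


def test_bandpass_is_linear():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=(2, 4000))
    lhs = bandpass(3.0 * x - 0.5 * y, FS, 300.0, 3000.0)
    rhs = 3.0 * bandpass(x, FS, 300.0, 3000.0) - 0.5 * bandpass(y, FS, 300.0, 3000.0)
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)


def test_band_edges_validated():
    with pytest.raises(ValueError, match="Nyquist"):
        bandpass(np.zeros(100), FS, 300.0, 9000.0)


# ---------------------------------------------------------------------------
# ECG


def test_ecg_detection_recovers_rate_and_count():
    cfg = SynthConfig(seed=21, duration=60.0, ecg=EcgSpec(rate=3.5))
    recording, _, manifest = generate_session(cfg)
    summary = detect_ecg(recording)
    assert len(summary.beat_indices) == len(manifest.beat_times)
    assert summary.heart_rate == pytest.approx(3.5, rel=0.02)
    assert summary.plausible
    assert summary.template.size > 0


def test_no_beats_in_pure_noise():
    cfg = SynthConfig(seed=22, duration=20.0, ecg=EcgSpec(amplitude_in_abr_band=0.0),
                      kernel=AbrKernelSpec(true_threshold_db=None))
    recording, _, _ = generate_session(cfg)
    with pytest.warns(UserWarning, match="fewer than 2 heartbeats"):
        summary = detect_ecg(recording)
    assert len(summary.beat_indices) == 0


# ---------------------------------------------------------------------------
# Epoching


def _make_recording(n_samples, channels=("LV", "RV", "LR")):
    rng = np.random.default_rng(0)
    return RawRecording(rng.normal(size=(len(channels), n_samples)), FS, channels)


def test_epoch_window_is_160_samples_at_16khz():
    rec = _make_recording(16000)
    train = StimulusTrain([5000, 7000], [1, -1], [73.0, 73.0], FS)
    tensor = epoch(rec, train)
    assert tensor.epochs.shape == (3, 2, 160)
    assert tensor.time[0] == pytest.approx(-0.0025)
    assert tensor.time[40] == 0.0
    # half-open window: 40 samples before, 120 from the onset on
    np.testing.assert_array_equal(tensor.epochs[0, 0], rec.samples[0, 4960:5120])


def test_epoch_boundary_trials():
    rec = _make_recording(160)
    train = StimulusTrain([40], [1], [73.0], FS)
    tensor = epoch(rec, train)  # exactly fits
    assert tensor.n_trials == 1 and tensor.n_clipped == 0

    train = StimulusTrain([0, 40], [1, 1], [73.0, 73.0], FS)
    tensor = epoch(rec, train)  # onset at 0 cannot supply the baseline
    assert tensor.n_trials == 1 and tensor.n_clipped == 1

    with pytest.raises(ValueError, match="no complete trials"):
        epoch(rec, StimulusTrain([0], [1], [73.0], FS))


# ---------------------------------------------------------------------------
# Outlier rejection


def _tensor_from_trials(trials):
    trials = np.asarray(trials)
    n = trials.shape[0]
    return TrialTensor(
        epochs=trials[None, :, :],
        channel_labels=("LV",),
        time=(np.arange(trials.shape[1]) - 40) / FS,
        levels_db=np.full(n, 73.0),
        polarities=np.ones(n, dtype=np.int64),
        onsets=np.arange(n) * 2000 + 1000,
        inclusion_mask=np.ones(n, dtype=bool),
        sampling_rate=FS,
    )


def test_identical_trials_are_never_rejected():
    tensor = _tensor_from_trials(np.tile(np.sin(np.arange(160)), (20, 1)))
    tensor, report = reject_outliers(tensor)
    assert tensor.inclusion_mask.all()
    assert report.empty


def test_gross_outlier_is_rejected():
    rng = np.random.default_rng(0)
    trials = rng.normal(size=(100, 160))
    trials[17] *= 100.0
    tensor = _tensor_from_trials(trials)
    tensor, report = reject_outliers(tensor)
    assert not tensor.inclusion_mask[17]
    assert set(report["trial"]) == {17}


def test_rejection_is_permutation_equivariant():
    rng = np.random.default_rng(1)
    trials = rng.normal(size=(60, 160))
    trials[5] *= 30
    trials[40] *= 25
    base = reject_outliers(_tensor_from_trials(trials))[0].inclusion_mask
    perm = rng.permutation(60)
    permuted = reject_outliers(_tensor_from_trials(trials[perm]))[0].inclusion_mask
    np.testing.assert_array_equal(permuted, base[perm])


def test_rejection_never_resurrects_trials():
    rng = np.random.default_rng(2)
    tensor = _tensor_from_trials(rng.normal(size=(30, 160)))
    tensor.inclusion_mask[3] = False
    tensor, _ = reject_outliers(tensor)
    assert not tensor.inclusion_mask[3]


def test_injected_outliers_rejected_with_few_false_positives():
    cfg = SynthConfig(seed=23, duration=30.0)
    recording, train, manifest = generate_session(cfg)
    recording, manifest = inject_outlier_trials(recording, train, manifest, n_outliers=5, scale=10.0, seed=3)
    filtered = bandpass_recording(recording, 300.0, 3000.0)
    tensor = epoch(filtered, train)
    tensor, _ = reject_outliers(tensor)
    rejected = set(np.flatnonzero(~tensor.inclusion_mask))
    injected = set(manifest.outlier_indices)
    assert injected <= rejected
    # trials overlapping a heartbeat are legitimately rejected; the false
    # positives are rejections among the remaining clean trials
    onset_t = tensor.onsets / FS
    ecg_hit = np.zeros(tensor.n_trials, dtype=bool)
    for tb in manifest.beat_times:
        ecg_hit |= (tb < onset_t + 0.0075) & (tb + 0.020 > onset_t - 0.0025)
    clean = set(np.flatnonzero(~ecg_hit)) - injected
    false_rate = len(rejected & clean) / len(clean)
    assert false_rate < 0.02


def test_all_rejected_raises_with_recording_name():
    trials = np.zeros((5, 160))
    tensor = _tensor_from_trials(trials)
    tensor.inclusion_mask[:] = False
    tensor.metadata["recording_id"] = "rec-X"
    with pytest.raises(ValueError, match="rec-X"):
        reject_outliers(tensor)


# ---------------------------------------------------------------------------
# Averaging


def test_noiseless_average_equals_response_template():
    recording, train, _ = generate_session(noiseless_config())
    tensor = epoch(recording, train)  # no filtering: compare raw kernels
    avg = average_by_level(tensor)
    for li in range(len(avg.levels_db)):
        sel = tensor.levels_db == avg.levels_db[li]
        np.testing.assert_array_almost_equal(
            avg.data[:, li], tensor.epochs[:, sel][:, 0], decimal=20
        )


def test_baseline_rms_of_100_trial_average_within_printed_range():
    # single-trial band noise of 1.5 uV rms: averaging 100 trials should put
    # the baseline of the mean at or below 0.15 uV
    vals = []
    for seed in range(25):
        trials = band_noise_trials(100, rms=1.5e-6, seed=seed)
        mean = trials.mean(axis=0)
        time = (np.arange(160) - 40) / FS
        vals.append(baseline_rms(mean, time))
    assert np.mean(vals) <= 0.15e-6
    assert np.mean(vals) > 0.05e-6  # and not unrealistically small


def test_polarity_pooled_average_cancels_stimulus_artifact():
    cfg_art = noiseless_config(seed=30, duration=30.0, stimulus_artifact_gain=1.0e-6)
    rec_art, train, _ = generate_session(cfg_art)
    cfg_clean = noiseless_config(seed=30, duration=30.0)
    rec_clean, _, _ = generate_session(cfg_clean)
    avg_art = average_by_level(epoch(rec_art, train), by_polarity=True)
    avg_clean = average_by_level(epoch(rec_clean, train))
    # per-polarity averages differ by twice the artifact...
    li = int(np.argmax(avg_art.levels_db))
    pol_diff = np.max(np.abs(avg_art.polarity_data[1][0, li] - avg_art.polarity_data[-1][0, li]))
    assert pol_diff > 1.0e-6
    # ...but the pooled average is artifact-free to < 0.05 uV
    assert np.max(np.abs(avg_art.data - avg_clean.data)) < 0.05e-6


def test_channel_algebra_survives_pipeline(demo_averaged):
    # LR is generated as LV - RV plus its own instrumentation noise; after
    # averaging ~35 trials per level the three independent ~0.2 uV noise
    # floors leave a residual well under 2 uV at every sample
    lv = demo_averaged.data[demo_averaged.channel_labels.index("LV")]
    rv = demo_averaged.data[demo_averaged.channel_labels.index("RV")]
    lr = demo_averaged.data[demo_averaged.channel_labels.index("LR")]
    assert np.max(np.abs(lr - (lv - rv))) < 2.0e-6


def test_channel_algebra_exact_without_channel_noise():
    cfg = SynthConfig(seed=31, duration=20.0, channel_noise=False)
    recording, train, _ = generate_session(cfg)
    filtered = bandpass_recording(recording, 300.0, 3000.0)
    avg = average_by_level(epoch(filtered, train))
    lv, rv, lr = (avg.data[avg.channel_labels.index(c)] for c in ("LV", "RV", "LR"))
    assert np.max(np.abs(lr - (lv - rv))) < 1e-16


def test_pool_average_counts_all_included_trials(demo_session):
    recording, train, _ = demo_session
    tensor = epoch(bandpass_recording(recording, 300.0, 3000.0), train)
    avg = pool_average(tensor)
    assert avg.data.shape[1] == 1
    assert avg.n_trials[0] == tensor.inclusion_mask.sum()
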