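"""Synthetic ABR sessions with the statistical structure of real recordings.

The generator emulates, per differential channel, the ingredients the
pipeline must cope with: spectrally 1/f background noise, ~30 uV
electrocardiogram spikes at 3-4 Hz, ~100 uV breathing artifacts near 1 Hz,
stationary instrumentation noise calibrated to a target rms in the
300-3000 Hz analysis band, an optional polarity-flipping electrical
stimulus artifact, and a level-dependent evoked response.  The response is
a Gabor-like damped oscillation (1 kHz carrier, ~0.5 ms envelope) whose
most negative extremum sits near 1.4 ms and whose latency grows by
~6.9 us/dB as the click level decreases; a smaller second component near
2.1 ms differs in sign between the two ears so that the between-ear (LR)
channel carries a response of its own.

Channels follow the source model of differential recording: latent sources
V_L, V_R, V_V at the two ears and the vertex combine as LV = V_L - V_V,
RV = V_R - V_V, LR = V_L - V_R, each plus optional independent
instrumentation noise.  A speaker-voltage channel carries the click train
for onset detection.  A single master seed drives independent substreams
per component, so toggling one component leaves the others unchanged, and
the same seed always reproduces the session exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .acoustics import DEFAULT_LEVEL_GRID, StimulusTrain
from .metrics import MetricConfig, rolling_strength
from .preprocess import (
    PipelineConfig,
    RawRecording,
    design_bandpass,
    white_noise_band_gain,
)

__all__ = [
    "AbrKernelSpec",
    "EcgSpec",
    "SynthConfig",
    "GroundTruthManifest",
    "ConfigurationError",
    "generate_session",
    "inject_outlier_trials",
    "band_noise_trials",
    "pink_noise",
]


class ConfigurationError(ValueError):
    """Raised for generator configurations that cannot produce a valid session."""


@dataclass(frozen=True)
class AbrKernelSpec:
    """Shape and level dependence of the simulated evoked response.

    The response amplitude follows a soft-plus curve of the click level
    above ``true_threshold_db``, scaled so that the rolling-SD response
    strength at the loudest level is ``strength_at_top`` (3.45 uV, a
    typical primary-peak magnitude).  ``true_threshold_db=None`` disables
    the response entirely (noise-only sessions).
    """

    primary_peak_latency: float = 1.4e-3  # s; most negative extremum
    oscillation_period: float = 1.0e-3  # s; ~1 kHz carrier
    envelope_sigma: float = 0.5e-3  # s; Gaussian envelope width
    latency_slope: float = 6.9e-6  # s of added delay per dB below the top level
    true_threshold_db: float | None = 35.0
    strength_at_top: float = 3.45e-6  # V; scalar strength at the loudest level
    softplus_width_db: float = 4.0
    late_component_latency: float = 2.1e-3  # s; ear-antisymmetric component
    late_component_gain: float = 0.5  # relative to the primary component
    contralateral_gain: float = 1.05  # contralateral primary slightly larger


@dataclass(frozen=True)
class EcgSpec:
    """Heartbeat contaminant: rate, waveform width, and in-band amplitude."""

    rate: float = 3.5  # Hz
    amplitude_in_abr_band: float = 30e-6  # V; spike height after 300-3000 Hz filtering
    rate_jitter: float = 0.1  # fractional beat-interval jitter
    r_sigma: float = 0.8e-3  # s; sharp positive deflection
    s_sigma: float = 1.6e-3  # s; slower opposite deflection


@dataclass(frozen=True)
class SynthConfig:
    """Complete description of a simulated recording session."""

    seed: int = 0
    duration: float = 480.0  # s; yields ~3800 clicks, ~295 per level
    sampling_rate: float = 16000.0
    ici_min: float = 0.080  # s; truncated-exponential inter-click intervals
    ici_max: float = 0.200
    ici_scale: float = 0.075  # s; gives mean ~125 ms, i.e. ~8 Hz
    level_grid: tuple[int, ...] = DEFAULT_LEVEL_GRID
    kernel: AbrKernelSpec = field(default_factory=AbrKernelSpec)
    ecg: EcgSpec = field(default_factory=EcgSpec)
    breathing_amplitude: float = 1.0e-4  # V
    breathing_rate: float = 1.0  # Hz
    breathing_sigma: float = 0.15  # s; width of each breath bump
    background_rms: float = 1.0e-6  # V per latent source; 1/f-shaped
    abr_band_noise_rms: float = 1.25e-6  # V; total stationary rms per channel in the ABR band
    line_noise_amplitude: float = 1.0e-6  # V at line_noise_freq
    line_noise_freq: float = 60.0
    stimulus_artifact_gain: float = 0.0  # V peak at the loudest level; sign follows polarity
    speaker_side: str = "L"
    speaker_peak_voltage: float = 0.1  # V at the loudest level
    speaker_noise_rms: float = 1.0e-5
    channel_noise: bool = True  # independent instrumentation noise per channel
    abr_band: tuple[float, float] = (300.0, 3000.0)
    filter_order: int = 2
    subject_id: str = "sim-mouse"
    recording_id: str = "sim-rec-000"

    def __post_init__(self) -> None:
        if self.speaker_side not in ("L", "R"):
            raise ConfigurationError("speaker_side must be 'L' or 'R'")
        if not 0 < self.ici_min < self.ici_max:
            raise ConfigurationError("require 0 < ici_min < ici_max")


@dataclass
class GroundTruthManifest:
    """Everything the generator knows about a session, for use as a test oracle."""

    seed: int
    sampling_rate: float
    speaker_side: str
    onsets: np.ndarray
    polarities: np.ndarray
    levels_db: np.ndarray
    beat_times: np.ndarray
    true_threshold_db: float | None
    latency_slope: float
    primary_peak_latency: float
    outlier_indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        for k in ("onsets", "polarities", "levels_db", "beat_times", "outlier_indices"):
            d[k] = np.asarray(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Components


def pink_noise(rng: np.random.Generator, n: int, rms: float, fs: float, f_floor: float = 0.5) -> np.ndarray:
    """Gaussian noise with 1/f power spectral density above ``f_floor``."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, f_floor))
    shape[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def _gabor(t: np.ndarray, center: float, period: float, sigma: float) -> np.ndarray:
    """Damped cosine with its most negative extremum (-1) at ``center``."""
    dt = t - center
    return -np.cos(2.0 * np.pi * dt / period) * np.exp(-(dt**2) / (2.0 * sigma**2))


def _softplus(x: float) -> float:
    return float(np.log1p(np.exp(-abs(x))) + max(x, 0.0))


def _response_templates(config: SynthConfig) -> tuple[dict, dict]:
    """Per-level ipsilateral and contralateral response waveforms (V).

    Amplitudes are calibrated so that the rolling-SD strength of the
    noiseless ipsilateral epoch at the loudest level equals
    ``kernel.strength_at_top``.
    """
    k = config.kernel
    fs = config.sampling_rate
    top = float(max(config.level_grid))
    n_resp = int(round(0.006 * fs))
    tt = np.arange(n_resp) / fs

    def composite(delay: float) -> tuple[np.ndarray, np.ndarray]:
        prim = _gabor(tt, k.primary_peak_latency + delay, k.oscillation_period, k.envelope_sigma)
        late = _gabor(tt, k.late_component_latency + delay, k.oscillation_period, k.envelope_sigma)
        ips = prim + k.late_component_gain * late
        con = k.contralateral_gain * prim - k.late_component_gain * late
        return ips, con

    # calibration: strength of the unit ipsilateral response at the top level
    pcfg = PipelineConfig()
    pre = int(round(-pcfg.epoch_window[0] * fs))
    post = int(round(pcfg.epoch_window[1] * fs))
    unit_ips, _ = composite(0.0)
    epoch_wave = np.zeros(pre + post)
    m = min(post, n_resp)
    epoch_wave[pre : pre + m] = unit_ips[:m]
    mcfg = MetricConfig()
    trace = rolling_strength(epoch_wave, fs, mcfg)
    s_unit = trace[pre + int(round(mcfg.scalar_time * fs))]
    amp_top = k.strength_at_top / s_unit

    def amplitude(level: float) -> float:
        if k.true_threshold_db is None:
            return 0.0
        arg = (level - k.true_threshold_db) / k.softplus_width_db
        if arg < -6.0:
            return 0.0
        top_arg = (top - k.true_threshold_db) / k.softplus_width_db
        return amp_top * _softplus(arg) / _softplus(top_arg)

    ips_by_level, con_by_level = {}, {}
    for lev in config.level_grid:
        amp = amplitude(float(lev))
        delay = k.latency_slope * (top - float(lev))
        ips, con = composite(delay)
        ips_by_level[lev] = amp * ips
        con_by_level[lev] = amp * con
    return ips_by_level, con_by_level


def _bump_train(
    rng: np.random.Generator,
    n: int,
    fs: float,
    rate: float,
    jitter: float,
    template: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic repetition of a template; returns (signal, event times)."""
    out = np.zeros(n)
    duration = n / fs
    mean_iv = 1.0 / rate
    m = int(np.ceil(duration / mean_iv)) + 8
    intervals = mean_iv * (1.0 + jitter * rng.uniform(-1.0, 1.0, size=m))
    times = rng.uniform(0, mean_iv) + np.cumsum(intervals)
    times = times[times < duration]
    tlen = template.size
    for t in times:
        i = int(round(t * fs))
        seg = min(tlen, n - i)
        if seg > 0:
            out[i : i + seg] += template[:seg]
    return out, times


def _truncated_exponential(rng: np.random.Generator, size: int, scale: float, span: float) -> np.ndarray:
    """Inverse-CDF samples of an exponential truncated to [0, span)."""
    u = rng.random(size)
    return -scale * np.log1p(-u * (1.0 - np.exp(-span / scale)))


def generate_session(config: SynthConfig) -> tuple[RawRecording, StimulusTrain, GroundTruthManifest]:
    """Simulate one recording: raw channels, stimulus train, and ground truth.

    The output is fully determined by ``config.seed``.  Raises
    :class:`ConfigurationError` if the duration is too short to place at
    least one click per level.
    """
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    ss = np.random.SeedSequence(config.seed)
    names = ["clicks", "pink_L", "pink_R", "pink_V", "ecg", "breathing", "channel", "speaker", "line"]
    rngs = {name: np.random.default_rng(s) for name, s in zip(names, ss.spawn(len(names)))}

    # --- click train -------------------------------------------------------
    rng = rngs["clicks"]
    span = config.ici_max - config.ici_min
    m = int(np.ceil(config.duration / config.ici_min)) + 8
    icis = config.ici_min + _truncated_exponential(rng, m, config.ici_scale, span)
    times = 0.1 + np.cumsum(icis)
    times = times[times < config.duration - 0.010]
    n_clicks = times.size
    grid = np.asarray(config.level_grid)
    if n_clicks < grid.size:
        raise ConfigurationError(
            f"duration {config.duration} s yields {n_clicks} clicks; "
            f"need at least one per level ({grid.size} levels)"
        )
    onsets = np.round(times * fs).astype(np.int64)
    reps = int(np.ceil(n_clicks / grid.size))
    levels = rng.permutation(np.tile(grid, reps)[:n_clicks]).astype(np.float64)
    # balanced polarities within each level, in random order, so that the
    # plain per-level mean cancels a polarity-flipping artifact
    polarities = np.empty(n_clicks, dtype=np.int64)
    for lev in grid:
        idx = np.flatnonzero(levels == lev)
        pol = np.ones(idx.size, dtype=np.int64)
        pol[: idx.size // 2] = -1
        if idx.size % 2:
            pol[-1] = rng.choice([-1, 1])
        polarities[idx] = rng.permutation(pol)

    # --- latent sources ----------------------------------------------------
    v_l = pink_noise(rngs["pink_L"], n, config.background_rms, fs)
    v_r = pink_noise(rngs["pink_R"], n, config.background_rms, fs)
    v_v = pink_noise(rngs["pink_V"], n, config.background_rms, fs)

    sos = design_bandpass(*config.abr_band, fs, config.filter_order)
    # in-band rms of the stationary background per channel, measured before
    # transients (heartbeats, breaths, responses) are mixed in; the white
    # instrumentation noise later tops each channel up to the configured
    # in-band total
    stationary_band_rms = {}
    if config.channel_noise:
        for name, mix in (("LV", v_l - v_v), ("RV", v_r - v_v), ("LR", v_l - v_r)):
            stationary_band_rms[name] = float(np.sqrt(np.mean(sps.sosfiltfilt(sos, mix) ** 2)))
    beat_times = np.empty(0)
    if config.ecg.amplitude_in_abr_band > 0:
        e = config.ecg
        t_t = np.arange(int(round(0.020 * fs))) / fs - 0.005
        tmpl = np.exp(-(t_t**2) / (2 * e.r_sigma**2)) - 0.6 * np.exp(
            -((t_t - 0.0025) ** 2) / (2 * e.s_sigma**2)
        )
        padded = np.concatenate([np.zeros(4000), tmpl, np.zeros(4000)])
        peak_in_band = np.max(np.abs(sps.sosfiltfilt(sos, padded)))
        tmpl *= e.amplitude_in_abr_band / peak_in_band
        ecg_sig, beat_times = _bump_train(rngs["ecg"], n, fs, e.rate, e.rate_jitter, tmpl)
        v_v += ecg_sig
        v_l += 0.25 * ecg_sig  # slight left-ear pickup so LR also sees the heart

    if config.breathing_amplitude > 0:
        bt = np.arange(int(round(6 * config.breathing_sigma * fs))) / fs
        bump = config.breathing_amplitude * np.exp(
            -((bt - 3 * config.breathing_sigma) ** 2) / (2 * config.breathing_sigma**2)
        )
        breath, _ = _bump_train(rngs["breathing"], n, fs, config.breathing_rate, 0.1, bump)
        v_v += breath

    if config.line_noise_amplitude > 0:
        phase = rngs["line"].uniform(0, 2 * np.pi)
        v_v += config.line_noise_amplitude * np.sin(
            2 * np.pi * config.line_noise_freq * np.arange(n) / fs + phase
        )

    # --- evoked responses and stimulus artifact ----------------------------
    ips_tmpl, con_tmpl = _response_templates(config)
    top = float(grid.max())
    art_len = int(round(0.001 * fs))
    art_tmpl = np.exp(-np.arange(art_len) / (1.5e-4 * fs))
    ips_source, con_source = (v_l, v_r) if config.speaker_side == "L" else (v_r, v_l)
    for on, lev, pol in zip(onsets, levels, polarities):
        seg = min(ips_tmpl[int(lev)].size, n - on)
        if seg <= 0:
            continue
        ips_source[on : on + seg] += ips_tmpl[int(lev)][:seg]
        con_source[on : on + seg] += con_tmpl[int(lev)][:seg]
        if config.stimulus_artifact_gain > 0:
            a = config.stimulus_artifact_gain * pol * 10 ** ((lev - top) / 20.0)
            aseg = min(art_len, n - on)
            v_l[on : on + aseg] += a * art_tmpl[:aseg]
            v_r[on : on + aseg] += 0.6 * a * art_tmpl[:aseg]

    # --- differential channels with calibrated instrumentation noise ------
    lv = v_l - v_v
    rv = v_r - v_v
    lr = v_l - v_r
    if config.channel_noise:
        gain = white_noise_band_gain(fs, *config.abr_band, config.filter_order)
        crng = rngs["channel"]
        target = config.abr_band_noise_rms
        for name, chan in (("LV", lv), ("RV", rv), ("LR", lr)):
            deficit = target**2 - stationary_band_rms[name] ** 2
            if deficit <= 0:
                warnings.warn(
                    f"channel {name}: background in-band rms {stationary_band_rms[name]:.3g} V "
                    f"already exceeds the target {target:.3g} V; no instrumentation noise added"
                )
                continue
            chan += (np.sqrt(deficit) / gain) * crng.standard_normal(n)
    else:
        lr = lv - rv  # exact channel algebra when instrumentation noise is off

    speaker = rngs["speaker"].standard_normal(n) * config.speaker_noise_rms
    ring_t = np.arange(1, int(round(0.001 * fs))) / fs
    ring = np.sin(2 * np.pi * 2000.0 * ring_t) * np.exp(-ring_t / 3.0e-4)
    for on, lev, pol in zip(onsets, levels, polarities):
        amp = config.speaker_peak_voltage * 10 ** ((lev - top) / 20.0)
        speaker[on] += pol * amp
        seg = min(ring.size, n - on - 1)
        if seg > 0:
            speaker[on + 1 : on + 1 + seg] += 0.5 * pol * amp * ring[:seg]

    recording = RawRecording(
        samples=np.vstack([lv, rv, lr, speaker]),
        sampling_rate=fs,
        channel_labels=("LV", "RV", "LR", "speaker"),
        metadata={
            "subject_id": config.subject_id,
            "recording_id": config.recording_id,
            "speaker_side": config.speaker_side,
            "seed": config.seed,
        },
    )
    train = StimulusTrain(onsets, polarities, levels, fs)
    manifest = GroundTruthManifest(
        seed=config.seed,
        sampling_rate=fs,
        speaker_side=config.speaker_side,
        onsets=onsets,
        polarities=polarities,
        levels_db=levels,
        beat_times=beat_times,
        true_threshold_db=config.kernel.true_threshold_db,
        latency_slope=config.kernel.latency_slope,
        primary_peak_latency=config.kernel.primary_peak_latency,
    )
    return recording, train, manifest


def inject_outlier_trials(
    recording: RawRecording,
    train: StimulusTrain,
    manifest: GroundTruthManifest,
    n_outliers: int,
    scale: float = 10.0,
    seed: int = 0,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[RawRecording, GroundTruthManifest]:
    """Scale up randomly chosen trial epochs to exceed the rejection criteria.

    Returns a modified copy of the recording and a manifest whose
    ``outlier_indices`` names the injected trials.  A ``scale <= 1`` is
    allowed but warned about, since it may not trigger rejection.
    """
    if n_outliers > len(train):
        raise ValueError("cannot inject more outliers than there are trials")
    if scale <= 1:
        warnings.warn("outlier scale <= 1 may not exceed the rejection criteria")
    if n_outliers == 0:
        return recording, manifest
    rng = np.random.default_rng(seed)
    picks = np.sort(rng.choice(len(train), size=n_outliers, replace=False))
    fs = recording.sampling_rate
    pre = int(round(-config.epoch_window[0] * fs))
    post = int(round(config.epoch_window[1] * fs))
    samples = recording.samples.copy()
    electrode_rows = [recording.channel_labels.index(c) for c in recording.electrode_labels()]
    for ti in picks:
        on = train.onsets[ti]
        lo, hi = max(0, on - pre), min(recording.n_samples, on + post)
        for row in electrode_rows:
            samples[row, lo:hi] *= scale
    out_rec = RawRecording(samples, fs, recording.channel_labels, dict(recording.metadata))
    out_manifest = replace(manifest, outlier_indices=picks.astype(np.int64))
    return out_rec, out_manifest


def band_noise_trials(
    n_trials: int,
    rms: float = 1.5e-6,
    n_samples: int = 160,
    sampling_rate: float = 16000.0,
    seed: int = 0,
    band: tuple[float, float] = (300.0, 3000.0),
    order: int = 2,
) -> np.ndarray:
    """No-signal trials whose band-filtered noise has the given rms.

    A continuous white-noise record is band filtered once (as the pipeline
    would filter a raw recording) and cut into consecutive trials, so the
    trials carry the filter's autocorrelation just like epochs cut from a
    real recording.  The scaling is exact in expectation for white noise.
    """
    pad = 2 * n_samples + 256
    total = n_trials * n_samples + 2 * pad
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(total)
    sos = design_bandpass(*band, sampling_rate, order)
    gain = white_noise_band_gain(sampling_rate, *band, order)
    x = sps.sosfiltfilt(sos, white) * (rms / gain)
    return x[pad : pad + n_trials * n_samples].reshape(n_trials, n_samples)
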