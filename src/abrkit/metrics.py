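"""Response quantification: rolling-SD response strength, interpolated
hearing thresholds, primary-peak extraction, level-dependent latency shifts,
across-session waveform correlations, threshold shifts, and the averaging
noise-floor law.

The central statistic is the "response strength": the rolling standard
deviation of the trial-averaged waveform over a 1.25 ms centered window.
It is peak-agnostic - it does not require identifying or labelling
individual waves - and it reduces to the local rms amplitude of the evoked
oscillation.  A scalar strength is read at t = +2.0 ms after click onset
(where the rolling SD tends to peak) and a baseline strength at
t = -1.875 ms, whose window spans the pre-stimulus baseline.  The hearing
threshold is the sound level at which strength crosses a fixed 0.3 uV
criterion, linearly interpolated between tested levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import AveragedABR

__all__ = [
    "MetricConfig",
    "StrengthCurve",
    "ThresholdEstimate",
    "PeakEstimate",
    "LatencyFit",
    "CorrelationSummary",
    "ShiftSummary",
    "NoiseFloorCurve",
    "rolling_strength",
    "strength_curves",
    "estimate_threshold",
    "find_primary_peak",
    "latency_shift",
    "waveform_correlation",
    "threshold_shift",
    "noise_floor_curve",
]


@dataclass(frozen=True)
class MetricConfig:
    strength_window: float = 0.00125  # s, rolling-SD window
    scalar_time: float = 0.0020  # s after onset; where strength peaks
    baseline_time: float = -0.001875  # s; window covers the baseline period
    threshold_criterion: float = 3.0e-7  # V; strength criterion for threshold
    peak_search_window: tuple[float, float] = (0.0005, 0.0025)  # s

    def __post_init__(self) -> None:
        if self.strength_window <= 0:
            raise ValueError("strength_window must be positive")
        if self.threshold_criterion <= 0:
            raise ValueError("threshold_criterion must be positive")


def rolling_strength(
    waveform: np.ndarray,
    sampling_rate: float,
    config: MetricConfig = MetricConfig(),
) -> np.ndarray:
    """Rolling sample standard deviation (ddof=1) over a centered window.

    The window length is ``round(strength_window * fs)`` samples (20 at
    16 kHz).  For an even window the nominal center sits half a sample early
    in the window: sample ``i`` summarizes ``x[i - w//2 : i + w - w//2]``.
    Edge positions where the full window does not fit are NaN.
    """
    x = np.asarray(waveform, dtype=np.float64)
    w = int(round(config.strength_window * sampling_rate))
    if w < 2:
        raise ValueError("strength window shorter than 2 samples")
    if w > x.shape[-1]:
        raise ValueError("strength window longer than the waveform")
    windows = np.lib.stride_tricks.sliding_window_view(x, w, axis=-1)
    sd = windows.std(axis=-1, ddof=1)
    out = np.full(x.shape, np.nan)
    half = w // 2
    out[..., half : half + sd.shape[-1]] = sd
    return out


@dataclass
class StrengthCurve:
    """Strength traces plus scalar and baseline readouts per (channel, level)."""

    traces: np.ndarray  # channels x levels x time
    scalar: np.ndarray  # channels x levels, strength at scalar_time
    baseline: np.ndarray  # channels x levels, strength at baseline_time
    channel_labels: tuple[str, ...]
    levels_db: np.ndarray
    time: np.ndarray


def _nearest_defined(trace: np.ndarray, time: np.ndarray, t: float) -> float:
    defined = np.flatnonzero(~np.isnan(trace))
    if defined.size == 0:
        return np.nan
    i = defined[np.argmin(np.abs(time[defined] - t))]
    return float(trace[i])


def strength_curves(avg: AveragedABR, config: MetricConfig = MetricConfig()) -> StrengthCurve:
    """Rolling-SD strength of every averaged waveform, with scalar readouts."""
    n_ch, n_lev, _ = avg.data.shape
    traces = rolling_strength(avg.data, avg.sampling_rate, config)
    scalar = np.empty((n_ch, n_lev))
    base = np.empty((n_ch, n_lev))
    for ci in range(n_ch):
        for li in range(n_lev):
            scalar[ci, li] = _nearest_defined(traces[ci, li], avg.time, config.scalar_time)
            base[ci, li] = _nearest_defined(traces[ci, li], avg.time, config.baseline_time)
    return StrengthCurve(traces, scalar, base, avg.channel_labels, avg.levels_db, avg.time)


@dataclass
class ThresholdEstimate:
    """Interpolated dB SPL threshold, possibly censored at the level grid."""

    threshold_db: float
    censoring: str = "none"  # "none" | "below_grid" | "above_grid"
    level_below: float | None = None
    level_above: float | None = None

    @property
    def censored(self) -> bool:
        return self.censoring != "none"


def estimate_threshold(
    levels_db: np.ndarray,
    strengths: np.ndarray,
    config: MetricConfig = MetricConfig(),
    space: str = "linear",
) -> ThresholdEstimate:
    """Sound level at which response strength crosses the fixed criterion.

    Levels are scanned in ascending order for the highest-level upward
    crossing: the last level with strength below the criterion whose next
    tested level reaches it.  The threshold is linearly interpolated between
    those two levels (``space="log"`` interpolates log strength instead).
    Using the highest-level crossing is robust to spurious bumps at low
    levels.  If strength meets the criterion at every level the threshold is
    censored below the grid; if it never does, above the grid.
    """
    levels = np.asarray(levels_db, dtype=np.float64)
    s = np.asarray(strengths, dtype=np.float64)
    ok = ~np.isnan(s)
    levels, s = levels[ok], s[ok]
    if levels.size < 2:
        raise ValueError("threshold estimation requires at least 2 levels")
    order = np.argsort(levels)
    levels, s = levels[order], s[order]
    c = config.threshold_criterion
    if (s >= c).all():
        return ThresholdEstimate(float(levels[0]), "below_grid")
    if (s < c).all():
        return ThresholdEstimate(float(levels[-1]), "above_grid")
    crossings = np.flatnonzero((s[:-1] < c) & (s[1:] >= c))
    if crossings.size == 0:
        # strength starts above the criterion and falls below for good
        return ThresholdEstimate(float(levels[-1]), "above_grid")
    i = int(crossings[-1])
    l0, l1 = levels[i], levels[i + 1]
    if space == "log":
        s0, s1, cc = np.log(s[i]), np.log(s[i + 1]), np.log(c)
    else:
        s0, s1, cc = s[i], s[i + 1], c
    thr = l0 + (cc - s0) * (l1 - l0) / (s1 - s0)
    return ThresholdEstimate(float(thr), "none", float(l0), float(l1))


@dataclass
class PeakEstimate:
    """Primary-peak latency and (negative) amplitude."""

    latency: float  # s
    amplitude: float  # V, negative under the ear-positive convention
    found: bool = True


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-sample extremum via a parabola through (i-1, i, i+1).

    Returns (fractional index offset in [-0.5, 0.5], interpolated value).
    """
    a, b, c = y[i - 1], y[i], y[i + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return 0.0, float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    value = b - 0.25 * (a - c) * delta
    return delta, float(value)


def find_primary_peak(
    waveform: np.ndarray,
    time: np.ndarray,
    config: MetricConfig = MetricConfig(),
) -> PeakEstimate:
    """Locate the large early negative deflection of the averaged ABR.

    The most negative sample within the search window (0.5-2.5 ms by
    default) is refined by parabolic interpolation over three samples.  If
    the minimum sits at the window edge (monotone waveform) or is not
    negative, no peak is reported.
    """
    x = np.asarray(waveform, dtype=np.float64)
    t = np.asarray(time, dtype=np.float64)
    lo, hi = config.peak_search_window
    win = np.flatnonzero((t >= lo) & (t <= hi))
    if win.size < 3:
        raise ValueError("peak search window contains fewer than 3 samples")
    seg = x[win]
    j = int(np.argmin(seg))
    i = int(win[j])
    at_edge = j == 0 or j == seg.size - 1
    if at_edge or seg[j] >= 0 or i == 0 or i == x.size - 1:
        return PeakEstimate(np.nan, np.nan, found=False)
    delta, value = _parabolic_refine(x, i)
    dt = t[1] - t[0]
    return PeakEstimate(float(t[i] + delta * dt), value, found=True)


@dataclass
class LatencyFit:
    """Per-level lag relative to the loudest level and its linear fit."""

    levels_db: np.ndarray  # levels used in the fit
    lags: np.ndarray  # s; 0 at the loudest level by definition
    slope: float  # s per dB of attenuation below the loudest level
    intercept: float  # s
    excluded_levels: np.ndarray
    peak_correlations: np.ndarray


def latency_shift(
    waveforms: np.ndarray,
    levels_db: np.ndarray,
    sampling_rate: float,
    min_corr: float = 0.3,
    max_lag: float = 0.0006,
) -> LatencyFit:
    """Delay of the response at each level relative to the loudest level.

    The lag is the argmax of the normalized cross-correlation against the
    loudest-level waveform, refined by parabolic interpolation - the sample
    period (62.5 us at 16 kHz) is coarse relative to the ~7 us/dB latency
    slope, so sub-sample estimation is essential.  The search range
    ``max_lag`` (default 0.6 ms) comfortably covers the expected delay span
    while staying below the ~1 ms oscillation period, so a peak one cycle
    off lands outside the range.  Levels whose peak correlation falls below
    ``min_corr`` (no detectable response) or whose correlation peaks at the
    search-range edge are excluded with a warning.
    The slope is the least-squares fit of lag against dB of attenuation
    below the loudest level.
    """
    w = np.asarray(waveforms, dtype=np.float64)
    levels = np.asarray(levels_db, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != levels.size:
        raise ValueError("waveforms must be (n_levels, n_samples)")
    if levels.size < 3:
        raise ValueError("latency fit requires at least 3 levels")
    top_i = int(np.argmax(levels))
    ref = w[top_i] - w[top_i].mean()
    ref_norm = np.linalg.norm(ref)
    max_k = max(1, int(round(max_lag * sampling_rate)))
    used_levels, lags, corrs, excluded = [], [], [], []
    for li, lev in enumerate(levels):
        y = w[li] - w[li].mean()
        y_norm = np.linalg.norm(y)
        if y_norm == 0 or ref_norm == 0:
            excluded.append(lev)
            continue
        c = np.correlate(y, ref, mode="full") / (ref_norm * y_norm)
        mid = w.shape[1] - 1  # zero-lag index; positive lag = y delayed
        seg = c[mid - max_k : mid + max_k + 1]
        j = int(np.argmax(seg))
        if j == 0 or j == seg.size - 1:
            warnings.warn(f"correlation peak at search edge for level {lev} dB; excluded")
            excluded.append(lev)
            continue
        if seg[j] < min_corr:
            excluded.append(lev)
            continue
        delta, _ = _parabolic_refine(seg, j)
        lag = (j - max_k + delta) / sampling_rate
        used_levels.append(lev)
        lags.append(0.0 if li == top_i else float(lag))
        corrs.append(float(seg[j]))
    used = np.asarray(used_levels)
    lags_arr = np.asarray(lags)
    if used.size < 3:
        raise ValueError("fewer than 3 levels with a detectable response")
    atten = levels[top_i] - used
    slope, intercept = np.polyfit(atten, lags_arr, 1)
    return LatencyFit(used, lags_arr, float(slope), float(intercept), np.asarray(excluded), np.asarray(corrs))


@dataclass
class CorrelationSummary:
    """Pearson correlations between two sets of session waveforms."""

    matrix: np.ndarray  # rows: first set, columns: second set
    within_mean: float
    within_sd: float
    across_mean: float
    across_sd: float
    undefined: list


def waveform_correlation(day1: np.ndarray, day2: np.ndarray) -> CorrelationSummary:
    """Pearson r between session waveforms of matched subjects.

    ``day1`` and ``day2`` are (n_subjects, n_features) arrays of flattened
    loudest-level waveforms in matched subject order.  Diagonal entries are
    within-subject (same animal on both days); off-diagonal entries are
    across-subject.  Zero-variance waveforms yield NaN and are flagged.
    """
    a = np.atleast_2d(np.asarray(day1, dtype=np.float64))
    b = np.atleast_2d(np.asarray(day2, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("day1 and day2 must have matching shapes")
    n = a.shape[0]
    mat = np.full((n, n), np.nan)
    undefined = []
    for i in range(n):
        for j in range(n):
            x, y = a[i], b[j]
            if np.std(x) == 0 or np.std(y) == 0:
                undefined.append((i, j))
                continue
            mat[i, j] = np.corrcoef(x, y)[0, 1]
    diag = np.diag(mat)
    off = mat[~np.eye(n, dtype=bool)]
    return CorrelationSummary(
        matrix=mat,
        within_mean=float(np.nanmean(diag)),
        within_sd=float(np.nanstd(diag, ddof=1)) if n > 1 else np.nan,
        across_mean=float(np.nanmean(off)) if n > 1 else np.nan,
        across_sd=float(np.nanstd(off, ddof=1)) if off.size > 1 else np.nan,
        undefined=undefined,
    )


@dataclass
class ShiftSummary:
    """Pre/post threshold comparison across subjects."""

    per_subject: dict  # subject -> shift in dB (point estimate or bound)
    lower_bound_subjects: list  # subjects where the shift is only a lower bound
    mean: float
    sd: float


def threshold_shift(pre: dict, post: dict) -> ShiftSummary:
    """Mean threshold change from pre- to post-manipulation sessions.

    ``pre`` and ``post`` map subject id to a sequence of
    :class:`ThresholdEstimate` (e.g., one per channel and speaker side).
    The shift for each subject is ``mean(post) - mean(pre)``.  Estimates
    censored above the level grid enter at the grid maximum and mark the
    subject's shift as a lower bound.  Summary mean and SD are taken across
    subjects.
    """
    if set(pre) != set(post):
        raise ValueError(f"subject sets differ: {sorted(set(pre) ^ set(post))}")
    per_subject = {}
    bounded = []
    for subject in sorted(pre):
        pre_vals = [e.threshold_db for e in pre[subject]]
        post_vals = [e.threshold_db for e in post[subject]]
        if not pre_vals or not post_vals:
            raise ValueError(f"subject {subject!r} has no threshold estimates")
        shift = float(np.mean(post_vals) - np.mean(pre_vals))
        per_subject[subject] = shift
        if any(e.censoring == "above_grid" for e in post[subject]):
            bounded.append(subject)
    shifts = np.array(list(per_subject.values()))
    sd = float(np.std(shifts, ddof=1)) if shifts.size > 1 else np.nan
    return ShiftSummary(per_subject, bounded, float(np.mean(shifts)), sd)


@dataclass
class NoiseFloorCurve:
    """Baseline rms of the n-trial average as a function of n."""

    n_trials: np.ndarray
    rms: np.ndarray
    slope: float  # log-log slope; -1/2 for independent trials


def noise_floor_curve(
    trials: np.ndarray,
    time: np.ndarray,
    baseline_window: tuple[float, float] = (-0.0025, -0.00125),
    n_grid: np.ndarray | None = None,
    n_repeats: int = 32,
    seed: int = 0,
) -> NoiseFloorCurve:
    """Measure how averaging suppresses baseline noise.

    For each n in a doubling grid, ``n_repeats`` random subsamples of n
    trials (without replacement, seeded) are averaged and the rms of the
    average over the baseline window is computed; the curve is the mean over
    repeats.  For independent trials the log-log slope is -1/2 (the law of
    large numbers); perfectly correlated trials give slope 0.
    """
    x = np.asarray(trials, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("trials must be (n_trials, n_samples)")
    n_total = x.shape[0]
    if n_total < 16:
        raise ValueError("noise floor curve requires at least 16 trials")
    t = np.asarray(time)
    bidx = np.flatnonzero((t >= baseline_window[0] - 1e-12) & (t < baseline_window[1] - 1e-12))
    if n_grid is None:
        n_grid = 4 * 2 ** np.arange(0, 16)
    n_grid = np.asarray(n_grid, dtype=np.int64)
    if (n_grid > n_total).any():
        warnings.warn(f"n grid truncated to the {n_total} available trials")
        n_grid = n_grid[n_grid <= n_total]
    rng = np.random.default_rng(seed)
    base = x[:, bidx]
    rms_vals = []
    for n in n_grid:
        acc = []
        for _ in range(n_repeats):
            pick = rng.choice(n_total, size=int(n), replace=False)
            avg = base[pick].mean(axis=0)
            acc.append(np.sqrt(np.mean(avg**2)))
        rms_vals.append(float(np.mean(acc)))
    rms_arr = np.asarray(rms_vals)
    slope = float(np.polyfit(np.log(n_grid), np.log(rms_arr), 1)[0]) if len(n_grid) >= 2 else np.nan
    return NoiseFloorCurve(n_grid, rms_arr, slope)
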