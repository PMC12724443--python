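# Methods

This note documents the models, parameter choices and numerical decisions
behind `abrkit`, and what the synthetic-data tests do and do not establish
about real recordings.

## Device model (`device_codec`)

The acquisition front end is modelled after the ADS1299 at its maximum
gain of 24 with a 4.5 V reference: full-scale input ±187.5 mV, and an LSB
of 2·FS/2²⁴ ≈ 22.35 nV, i.e. almost seven orders of magnitude of dynamic
range.  The reference voltage is not printed in the device's deployment
notes we follow; 4.5 V is inferred because it reproduces the ±187 mV /
22 nV pair exactly and is the chip's standard internal reference.  Frames
follow the chip's documented continuous-read output (24-bit status word,
then one big-endian two's-complement 24-bit word per channel); status words
are retained but not interpreted (no lead-off logic).  The passive input
filter is an RC lowpass, f_c = 1/(2πRC) ≈ 3.39 kHz for a 10 kΩ electrode
and the 4.7 nF input capacitor — just above the analysis band, so it is
modelled but never applied digitally.

## Acoustics (`acoustics`)

Click level treats the maximum peak-to-peak pressure divided by 100 (the
50 ms auditory integration window over the 0.5 ms click duration) as the
effective pressure re 20 µPa.  An rms-over-window variant is provided
(`mode="rms"`); for these stimuli the two agree to within a couple of dB.
Levels are nominal: no per-level empirical speaker calibration is applied.
The speed of sound is fixed at 343 m/s (20 °C, configurable).  Trial time
zero is speaker onset; the ~0.39 ms free-field propagation delay to the ear
is computable but deliberately **not** subtracted, so reported latencies
include it.

Click-onset detection on the recorded speaker-voltage channel thresholds at
5 robust SDs (MAD-based), groups crossings with a 50 ms refractory period
(well below the ~125 ms inter-click interval), takes the onset as the first
sample reaching 10% of the event peak, and the polarity as the sign at the
onset.  This is a deterministic stand-in for an unspecified procedure; on
simulated sessions it recovers onsets and polarities exactly.

## Synthetic sessions (`synthesize`)

The generator's defaults are the study conditions the pipeline assumes:

| parameter | default | rationale |
|---|---|---|
| sampling rate | 16 kHz | device rate |
| click train | truncated-exponential ICIs on [80, 200] ms, scale 75 ms | irregular, mean ≈125 ms → ~8 Hz |
| level grid | 25–73 dB SPL, 4 dB steps | 13 levels |
| in-band noise | 1.25 µV rms per channel (300–3000 Hz) | middle of the observed 1–1.5 µV range |
| background | 1/f-shaped, 1 µV rms per latent source | matches the raw-spectrum power law |
| ECG | 3.5 Hz ± 10% jitter, 30 µV in-band spikes | heartbeat contaminant |
| breathing | 1 Hz, 100 µV Gaussian bumps (σ = 0.15 s) | large low-frequency artifact |
| evoked kernel | Gabor, 1 kHz carrier, σ = 0.5 ms envelope, trough at 1.4 ms | wavelet-like response, ~1 ms period |
| latency slope | 6.9 µs per dB below the top level | level-dependent delay |
| amplitude vs level | soft-plus above a 35 dB true threshold, scaled to 3.45 µV strength at 73 dB | monotone growth; zero well below threshold |
| true threshold | 35 dB SPL | healthy-hearing default |

Channels follow the differential source model: LV = V_L − V_V,
RV = V_R − V_V, LR = V_L − V_R, each plus independent white
instrumentation noise.  The white noise per channel is calibrated so that
the *stationary* 300–3000 Hz rms (1/f background + white) equals the
configured target; the expectation-exact white-noise gain of the zero-phase
bandpass is computed from the filter's frequency response.  With channel
noise disabled, LR is produced as literally LV − RV, making the channel
algebra exact.  A second, smaller response component at 2.1 ms enters the
two ears with opposite sign, so the LR channel carries a genuine response
rather than a near-cancellation; the contralateral primary component is 5%
larger than the ipsilateral one.  The heartbeat source couples mostly
through the vertex electrode with a 25% pickup at the left ear (gains are
our invention; only the per-channel spike amplitude is constrained by
data), so all three channels see the ECG.

Polarities are drawn *exactly balanced* within each level (random order)
rather than independently per click.  This is a deliberate idealization:
it makes the plain per-level mean cancel the polarity-flipping electrical
stimulus artifact deterministically (residual ≤ artifact/n), which is the
property the averaging stage is supposed to exhibit.  Levels are likewise
a shuffled balanced tiling of the grid.

A single master seed spawns independent substreams per component (clicks,
each noise source, ECG, breathing, speaker), so disabling one component
does not perturb the others, and equal seeds give byte-identical sessions.

What the generator does **not** emulate: cochlear/brainstem biophysics
(the kernel shape is a convenience, not physiology), real electrode-
placement variability, line-noise harmonics and nonstationary artifacts,
speaker transfer functions, or inter-subject waveform diversity.  Passing
tests therefore demonstrate the *pipeline's* correctness under controlled
statistics, not the biological fidelity of any waveform.

## Pipeline (`preprocess`)

Filters are Butterworth designs of order 2 applied forward–backward
(`sosfiltfilt`).  Zero-phase application is essential — a causal 300 Hz
highpass would shift a 1.4 ms peak measurably — and doubles the effective
stopband attenuation relative to the nominal order.  Epochs are the
half-open sample window [onset − round(2.5 ms·fs), onset + round(7.5 ms·fs)),
160 samples at 16 kHz; edge-clipped trials are dropped, not padded.

Outlier rejection computes, per channel and trial, max |x| and rms over
the full epoch in one pass; a trial is dropped when either statistic
exceeds mean + 3 SD of that statistic over all trials of the recording
("typical" = mean; a median mode is available).  A trial rejected on any
channel is rejected on all channels, since the underlying artifact
(usually a heartbeat) is physiological and shared.  Rejection happens per
recording, before grouping by level, and the inclusion mask only shrinks.
Averages are plain arithmetic means of included trials per (channel,
level); per-polarity means are kept on request.  Baseline rms is measured
over −2.5 to −1.25 ms.

ECG detection thresholds the 20–500 Hz band at 6 robust SDs with a 100 ms
refractory period; heart rate is (beats − 1)/span, flagged (not an error)
outside 2–8 Hz.

## Metrics (`metrics`)

All standard deviations use ddof = 1 (rolling window and trial statistics).
The 1.25 ms rolling window is 20 samples at 16 kHz; for an even window the
nominal centre sits half a sample early (sample *i* summarizes
x[i−10 : i+10)), which places the baseline readout at t = −1.875 ms exactly
over the −2.5 to −1.31 ms baseline.  Scalar strength is read at the defined
sample nearest t = +2.0 ms.

Threshold interpolation is linear in (level, strength) as the criterion is
stated, with a log-strength option.  When strengths are non-monotone the
*highest-level* upward crossing is used, which is robust to spurious
low-level bumps.  Censoring: below_grid if every level meets the criterion,
above_grid if none does.

The latency-shift fit cross-correlates each level's average against the
loudest level, restricted to lags within ±0.6 ms: large enough for the
~0.33 ms delay accumulated over the 48 dB grid, but below the ~1 ms
oscillation period, so a correlation peak one cycle off lands on the search
edge and the level is excluded (as are levels with peak correlation
< 0.3 — no detectable response).  Sub-sample lags come from a 3-point
parabolic refinement; the 62.5 µs sample period would otherwise be far too
coarse for a ~7 µs/dB slope.  The primary peak is the most negative sample
in 0.5–2.5 ms, parabolically refined; positive-only or monotone waveforms
report "no peak".

Threshold shifts are mean(post) − mean(pre) per subject, then mean ± SD
across subjects; post-estimates censored above the grid make the subject's
shift a lower bound and are flagged as such.

## Problem sizes used in tests and the acceptance script

Simulated sessions are scaled to keep statistical power while staying
desk-size: the averaging noise law uses 25 runs of 100 trials plus a
300-trial subsampling curve (slope −0.5 ± 0.05); the false-positive
control uses 1000 independent 15 s noise-only recordings (~115 trials
each); threshold recovery uses 180 s sessions (~110 trials/level) over
10 seeds × 3 true thresholds; the latency-slope recovery uses one 300 s
session.  These are the package's reference conditions; longer recordings
only tighten the numbers (noise falls as n^−1/2).

## Known limitations

- Nominal click levels are trusted; a ±2 dB speaker nonlinearity would
  propagate directly into thresholds.
- The 0.3 µV criterion and the 2.0 ms scalar time are fixed conventions;
  both are configurable but results are only comparable at fixed settings.
- Censored thresholds enter shift summaries at the grid edge (as bounds),
  which understates large shifts.
- The native file format stores float32 volts; raw 24-bit frame dumps are
  importable but not written back.
- No real-time display, impedance checking, or lead-off interpretation.
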