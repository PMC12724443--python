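"""On-disk formats, the experiment data model, and pipeline orchestration.

A recording is stored as a little-endian float32 binary payload in volts
(channel-major) next to a human-readable JSON sidecar carrying the format
version, sampling rate, channel labels and metadata.  Time is stored as
sample indices; seconds are always derived from the sampling rate.  A
session manifest groups the recordings of one anesthetic session (an
experiment normally holds at least two recordings per speaker side).

``run_pipeline`` chains the full offline analysis for each recording:
ABR-band filtering, epoching, outlier rejection, per-level averaging,
response-strength curves, interpolated thresholds, primary-peak extraction
and the latency-vs-level fit, and writes the results as CSV tables plus a
run log with a configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acoustics import StimulusTrain, read_stimulus_csv
from .metrics import (
    LatencyFit,
    MetricConfig,
    PeakEstimate,
    StrengthCurve,
    ThresholdEstimate,
    estimate_threshold,
    find_primary_peak,
    latency_shift,
    strength_curves,
)
from .preprocess import (
    AveragedABR,
    PipelineConfig,
    RawRecording,
    average_by_level,
    bandpass_recording,
    epoch,
    reject_outliers,
)

__all__ = [
    "FORMAT_VERSION",
    "RecordingEntry",
    "SessionManifest",
    "RecordingResult",
    "write_recording",
    "read_recording",
    "config_to_dict",
    "config_from_dict",
    "config_hash",
    "process_recording",
    "run_pipeline",
]

logger = logging.getLogger("abrkit")

FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Recording format


def write_recording(recording: RawRecording, basepath) -> None:
    """Write ``<base>.dat`` (float32 LE, channel-major, volts) + ``<base>.json``."""
    base = Path(basepath)
    payload = np.ascontiguousarray(recording.samples, dtype="<f4")
    base.with_suffix(".dat").write_bytes(payload.tobytes())
    header = {
        "format_version": FORMAT_VERSION,
        "sampling_rate": recording.sampling_rate,
        "channel_labels": list(recording.channel_labels),
        "n_samples": recording.n_samples,
        "units": "volts",
        "metadata": recording.metadata,
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_recording(basepath) -> RawRecording:
    """Read a recording written by :func:`write_recording`, with validation."""
    base = Path(basepath)
    header = json.loads(base.with_suffix(".json").read_text())
    version = header.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported recording format version {version!r} (expected {FORMAT_VERSION})")
    labels = header["channel_labels"]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate channel labels in header: {labels}")
    n_channels = len(labels)
    n_samples = int(header["n_samples"])
    payload = base.with_suffix(".dat").read_bytes()
    expected = n_channels * n_samples * 4
    if len(payload) != expected:
        raise ValueError(
            f"payload size mismatch for {base.name}: expected {expected} bytes "
            f"({n_channels} channels x {n_samples} samples x 4), found {len(payload)}"
        )
    samples = np.frombuffer(payload, dtype="<f4").reshape(n_channels, n_samples)
    return RawRecording(
        samples=samples.copy(),
        sampling_rate=float(header["sampling_rate"]),
        channel_labels=tuple(labels),
        metadata=header.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Experiment data model


@dataclass
class RecordingEntry:
    recording_id: str
    speaker_side: str
    duration: float
    recording_path: str
    stimulus_path: str

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"recording {self.recording_id!r} has nonpositive duration")
        if self.speaker_side not in ("L", "R"):
            raise ValueError(f"speaker side must be 'L' or 'R', got {self.speaker_side!r}")


@dataclass
class SessionManifest:
    """One anesthetic session: subject, date, and its recordings."""

    subject_id: str
    experiment_date: str
    recordings: list[RecordingEntry] = field(default_factory=list)
    exclusion_notes: str = ""

    def __post_init__(self) -> None:
        for side in ("L", "R"):
            count = sum(1 for r in self.recordings if r.speaker_side == side)
            if self.recordings and count < 2:
                warnings.warn(
                    f"session {self.subject_id}/{self.experiment_date}: only {count} "
                    f"recording(s) from speaker side {side} (2 or more expected)"
                )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "SessionManifest":
        d = json.loads(Path(path).read_text())
        d["recordings"] = [RecordingEntry(**r) for r in d["recordings"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# Configuration round-trip


def config_to_dict(config) -> dict:
    """Serialize a config dataclass (nested dataclasses included)."""
    d = dataclasses.asdict(config)
    d["__type__"] = type(config).__name__
    return d


def config_from_dict(d: dict):
    """Inverse of :func:`config_to_dict`; serialize(parse(x)) is a fixed point."""
    from . import synthesize  # local import to avoid a cycle at module load

    registry = {
        "PipelineConfig": PipelineConfig,
        "MetricConfig": MetricConfig,
        "SynthConfig": synthesize.SynthConfig,
        "AbrKernelSpec": synthesize.AbrKernelSpec,
        "EcgSpec": synthesize.EcgSpec,
    }
    d = dict(d)
    cls = registry[d.pop("__type__")]
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in d.items():
        if isinstance(value, list):
            value = tuple(value)
        if isinstance(value, dict) and "__type__" in value:
            value = config_from_dict(value)
        elif key == "kernel" and isinstance(value, dict):
            value = synthesize.AbrKernelSpec(**value)
        elif key == "ecg" and isinstance(value, dict):
            value = synthesize.EcgSpec(**value)
        kwargs[key] = value
    return cls(**kwargs)


def config_hash(*configs) -> str:
    blob = json.dumps([config_to_dict(c) for c in configs], sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RecordingResult:
    """All derived quantities for one recording."""

    recording_id: str
    speaker_side: str
    averaged: AveragedABR
    strengths: StrengthCurve
    thresholds: dict[str, ThresholdEstimate]
    peaks: dict[str, PeakEstimate]
    latency_fits: dict[str, LatencyFit]
    exclusions: pd.DataFrame
    n_trials_total: int
    n_trials_rejected: int

    def threshold_table(self) -> pd.DataFrame:
        rows = []
        for ch, est in self.thresholds.items():
            rows.append(
                {
                    "recording_id": self.recording_id,
                    "channel": ch,
                    "speaker_side": self.speaker_side,
                    "threshold_db": est.threshold_db,
                    "censoring": est.censoring,
                }
            )
        return pd.DataFrame(rows)

    def strength_table(self) -> pd.DataFrame:
        rows = []
        sc = self.strengths
        for ci, ch in enumerate(sc.channel_labels):
            for li, lev in enumerate(sc.levels_db):
                rows.append(
                    {
                        "recording_id": self.recording_id,
                        "channel": ch,
                        "speaker_side": self.speaker_side,
                        "level_db": lev,
                        "strength_uV": sc.scalar[ci, li] * 1e6,
                        "baseline_uV": sc.baseline[ci, li] * 1e6,
                    }
                )
        return pd.DataFrame(rows)

    def peak_table(self) -> pd.DataFrame:
        rows = []
        for ch, pk in self.peaks.items():
            rows.append(
                {
                    "recording_id": self.recording_id,
                    "channel": ch,
                    "speaker_side": self.speaker_side,
                    "latency_ms": pk.latency * 1e3 if pk.found else np.nan,
                    "amplitude_uV": pk.amplitude * 1e6 if pk.found else np.nan,
                    "found": pk.found,
                }
            )
        return pd.DataFrame(rows)


def process_recording(
    recording: RawRecording,
    train: StimulusTrain,
    pipeline_config: PipelineConfig | None = None,
    metric_config: MetricConfig | None = None,
) -> RecordingResult:
    """Run the per-recording analysis chain on in-memory objects."""
    pcfg = pipeline_config or PipelineConfig()
    mcfg = metric_config or MetricConfig()
    rec_id = recording.metadata.get("recording_id", "<unnamed>")
    try:
        filtered = bandpass_recording(recording, *pcfg.abr_band, pcfg.filter_order)
        tensor = epoch(filtered, train, pcfg)
        n_total = tensor.n_trials
        tensor, exclusions = reject_outliers(tensor, pcfg.rejection_sigmas)
        n_rejected = n_total - int(tensor.inclusion_mask.sum())
        averaged = average_by_level(tensor, pcfg)
        sc = strength_curves(averaged, mcfg)
        thresholds, peaks, fits = {}, {}, {}
        for ci, ch in enumerate(averaged.channel_labels):
            thresholds[ch] = estimate_threshold(averaged.levels_db, sc.scalar[ci], mcfg)
            top_li = int(np.argmax(averaged.levels_db))
            peaks[ch] = find_primary_peak(averaged.data[ci, top_li], averaged.time, mcfg)
            try:
                fits[ch] = latency_shift(
                    averaged.data[ci], averaged.levels_db, averaged.sampling_rate
                )
            except ValueError:
                logger.info("recording %s channel %s: no latency fit (undetectable response)", rec_id, ch)
    except Exception as err:
        raise RuntimeError(f"pipeline failed for recording {rec_id!r}: {err}") from err
    return RecordingResult(
        recording_id=rec_id,
        speaker_side=recording.metadata.get("speaker_side", "?"),
        averaged=averaged,
        strengths=sc,
        thresholds=thresholds,
        peaks=peaks,
        latency_fits=fits,
        exclusions=exclusions,
        n_trials_total=n_total,
        n_trials_rejected=n_rejected,
    )


def run_pipeline(
    manifest: SessionManifest,
    output_dir,
    pipeline_config: PipelineConfig | None = None,
    metric_config: MetricConfig | None = None,
    write_averages: bool = True,
) -> list[RecordingResult]:
    """Process every recording in a session manifest and write result tables.

    Outputs per session: ``thresholds.csv``, ``strengths.csv``, ``peaks.csv``,
    ``exclusions.csv``, per-recording averaged waveforms (optional), and
    ``run_log.json`` recording the configuration hash and package versions.
    Deterministic given identical inputs and configuration.
    """
    pcfg = pipeline_config or PipelineConfig()
    mcfg = metric_config or MetricConfig()
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not manifest.recordings:
        logger.warning("session %s has no recordings; nothing to do", manifest.subject_id)
        return []
    results = []
    for entry in manifest.recordings:
        recording = read_recording(entry.recording_path)
        recording.metadata.setdefault("recording_id", entry.recording_id)
        recording.metadata.setdefault("speaker_side", entry.speaker_side)
        recording.metadata.setdefault("subject_id", manifest.subject_id)
        train = read_stimulus_csv(entry.stimulus_path, recording.sampling_rate)
        result = process_recording(recording, train, pcfg, mcfg)
        results.append(result)
        if write_averages:
            result.averaged.to_frame().to_csv(out / f"averaged_{entry.recording_id}.csv", index=False)
    pd.concat([r.threshold_table() for r in results], ignore_index=True).to_csv(
        out / "thresholds.csv", index=False
    )
    pd.concat([r.strength_table() for r in results], ignore_index=True).to_csv(
        out / "strengths.csv", index=False
    )
    pd.concat([r.peak_table() for r in results], ignore_index=True).to_csv(out / "peaks.csv", index=False)
    pd.concat(
        [r.exclusions.assign(recording_id=r.recording_id) for r in results], ignore_index=True
    ).to_csv(out / "exclusions.csv", index=False)
    import numpy as _np
    import scipy as _sp

    log = {
        "subject_id": manifest.subject_id,
        "experiment_date": manifest.experiment_date,
        "n_recordings": len(results),
        "config_hash": config_hash(pcfg, mcfg),
        "versions": {"abrkit": __version__, "numpy": _np.__version__, "scipy": _sp.__version__},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
    return results
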