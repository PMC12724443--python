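"""Decoding of ADS1299 sample frames and conversion between ADC codes and volts.

The ADS1299 is a 24-bit, 8-channel differential biosignal amplifier.  In its
standard continuous-read mode every sample period produces one *frame* on the
SPI bus: a 24-bit status word followed by one big-endian two's-complement
24-bit data word per channel.  This module turns raw frame dumps into signed
integer codes, converts codes to volts using the device gain and reference
voltage, and models the passive RC pre-filter formed by the electrode
impedance and the input capacitor.

At the maximum gain of 24 with a 4.5 V reference the full-scale input is
+/-187 mV and one code step (LSB) is about 22 nV, giving almost seven orders
of magnitude of dynamic range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DeviceProfile",
    "FrameBlock",
    "MalformedStreamError",
    "DEFAULT_PROFILE",
    "parse_frames",
    "serialize_frames",
    "codes_to_volts",
    "volts_to_codes",
    "prefilter_cutoff",
    "read_frame_dump",
    "write_frame_dump",
]

_STATUS_BYTES = 3
_BYTES_PER_CHANNEL = 3


class MalformedStreamError(ValueError):
    """Raised when a frame payload does not divide into whole frames."""


@dataclass(frozen=True)
class DeviceProfile:
    """Static description of the acquisition front end.

    Parameters
    ----------
    reference_voltage : float
        ADC reference in volts.  4.5 V makes the printed +/-187 mV full
        scale and 22 nV resolution exact at gain 24.
    gain : float
        Programmable amplifier gain (dimensionless).
    adc_bits : int
        Converter resolution in bits.
    sampling_rate : float
        Samples per second per channel.
    n_channels : int
        Number of differential inputs.
    electrode_impedance : float
        Assumed source impedance in ohms; forms an RC lowpass with
        ``prefilter_capacitance``.
    prefilter_capacitance : float
        Input capacitor to ground, in farads.
    """

    reference_voltage: float = 4.5
    gain: float = 24.0
    adc_bits: int = 24
    sampling_rate: float = 16000.0
    n_channels: int = 8
    electrode_impedance: float = 1.0e4
    prefilter_capacitance: float = 4.7e-9

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.adc_bits < 2:
            raise ValueError("adc_bits must be at least 2")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")

    @property
    def full_scale(self) -> float:
        """Full-scale input amplitude in volts (one-sided)."""
        return self.reference_voltage / self.gain

    @property
    def lsb(self) -> float:
        """Voltage of one code step: the +/-full-scale span over 2**bits codes."""
        return 2.0 * self.full_scale / 2**self.adc_bits

    @property
    def code_min(self) -> int:
        return -(2 ** (self.adc_bits - 1))

    @property
    def code_max(self) -> int:
        return 2 ** (self.adc_bits - 1) - 1

    @property
    def dynamic_range(self) -> float:
        """Full-scale amplitude over LSB (~2**23 for a 24-bit converter)."""
        return self.full_scale / self.lsb


DEFAULT_PROFILE = DeviceProfile()


@dataclass
class FrameBlock:
    """Decoded block of consecutive sample frames."""

    codes: np.ndarray  # (frames, n_channels) int32, sign-extended
    status_words: np.ndarray  # (frames,) uint32, lower 24 bits valid
    n_channels: int

    @property
    def frames(self) -> int:
        return self.codes.shape[0]


def _frame_size(n_channels: int) -> int:
    return _STATUS_BYTES + _BYTES_PER_CHANNEL * n_channels


def _pack24(b: np.ndarray) -> np.ndarray:
    """Combine a (..., 3) uint8 array of big-endian bytes into unsigned ints."""
    b = b.astype(np.int64)
    return (b[..., 0] << 16) | (b[..., 1] << 8) | b[..., 2]


def parse_frames(payload: bytes, n_channels: int = 8) -> FrameBlock:
    """Decode a byte stream of concatenated ADS1299 frames.

    Each frame is a 3-byte status word followed by ``n_channels`` 3-byte
    big-endian two's-complement data words.  Frame order is preserved.

    Raises
    ------
    MalformedStreamError
        If the payload length is not a whole number of frames.  The message
        names the byte offset at which the partial frame begins.
    """
    fsize = _frame_size(n_channels)
    n_bytes = len(payload)
    if n_bytes % fsize != 0:
        offset = (n_bytes // fsize) * fsize
        raise MalformedStreamError(
            f"payload of {n_bytes} bytes is not a multiple of the "
            f"{fsize}-byte frame size for {n_channels} channels; "
            f"partial frame starts at byte offset {offset}"
        )
    raw = np.frombuffer(bytes(payload), dtype=np.uint8).reshape(-1, fsize)
    status = _pack24(raw[:, :_STATUS_BYTES]).astype(np.uint32)
    data = raw[:, _STATUS_BYTES:].reshape(-1, n_channels, _BYTES_PER_CHANNEL)
    codes = _pack24(data)
    codes = np.where(codes >= 1 << 23, codes - (1 << 24), codes).astype(np.int32)
    return FrameBlock(codes=codes, status_words=status, n_channels=n_channels)


def serialize_frames(block: FrameBlock) -> bytes:
    """Re-encode a FrameBlock to bytes; inverse of :func:`parse_frames`."""
    frames = block.frames
    fsize = _frame_size(block.n_channels)
    out = np.empty((frames, fsize), dtype=np.uint8)
    status = block.status_words.astype(np.int64)
    codes = block.codes.astype(np.int64) & 0xFFFFFF
    out[:, 0] = (status >> 16) & 0xFF
    out[:, 1] = (status >> 8) & 0xFF
    out[:, 2] = status & 0xFF
    data = out[:, _STATUS_BYTES:].reshape(frames, block.n_channels, 3)
    data[..., 0] = (codes >> 16) & 0xFF
    data[..., 1] = (codes >> 8) & 0xFF
    data[..., 2] = codes & 0xFF
    return out.tobytes()


def codes_to_volts(codes, profile: DeviceProfile = DEFAULT_PROFILE) -> np.ndarray:
    """Convert signed ADC codes to volts (``volts = code * lsb``)."""
    codes = np.asarray(codes)
    if codes.size and (codes.min() < profile.code_min or codes.max() > profile.code_max):
        raise ValueError(
            f"code out of range [{profile.code_min}, {profile.code_max}] "
            f"for a {profile.adc_bits}-bit converter"
        )
    return codes.astype(np.float64) * profile.lsb


def volts_to_codes(volts, profile: DeviceProfile = DEFAULT_PROFILE) -> np.ndarray:
    """Convert volts to the nearest ADC code; exact on integer multiples of the LSB."""
    volts = np.asarray(volts, dtype=np.float64)
    codes = np.rint(volts / profile.lsb).astype(np.int64)
    if codes.size and (codes.min() < profile.code_min or codes.max() > profile.code_max):
        raise ValueError("voltage exceeds the converter full scale")
    return codes.astype(np.int32)


def prefilter_cutoff(profile: DeviceProfile = DEFAULT_PROFILE) -> float:
    """-3 dB frequency of the passive input RC lowpass, ``1 / (2 pi R C)``.

    With a 10 kOhm electrode and the 4.7 nF input capacitor this is about
    3.4 kHz, just above the analysis band.
    """
    r = profile.electrode_impedance
    c = profile.prefilter_capacitance
    if r <= 0 or c <= 0:
        raise ValueError("electrode impedance and capacitance must be positive")
    return 1.0 / (2.0 * math.pi * r * c)


def write_frame_dump(path, block: FrameBlock, profile: DeviceProfile = DEFAULT_PROFILE) -> None:
    """Write a raw frame dump plus a JSON sidecar with the channel count."""
    path = Path(path)
    path.write_bytes(serialize_frames(block))
    sidecar = {
        "n_channels": block.n_channels,
        "sampling_rate": profile.sampling_rate,
        "reference_voltage": profile.reference_voltage,
        "gain": profile.gain,
        "adc_bits": profile.adc_bits,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_frame_dump(path) -> tuple[np.ndarray, DeviceProfile]:
    """Read a raw frame dump written by :func:`write_frame_dump`.

    Returns
    -------
    samples : ndarray, shape (n_channels, n_frames)
        Channel voltages in volts.
    profile : DeviceProfile
        Profile reconstructed from the sidecar (defaults filled in).
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text())
    profile = DeviceProfile(
        reference_voltage=meta.get("reference_voltage", 4.5),
        gain=meta.get("gain", 24.0),
        adc_bits=meta.get("adc_bits", 24),
        sampling_rate=meta.get("sampling_rate", 16000.0),
        n_channels=meta["n_channels"],
    )
    block = parse_frames(path.read_bytes(), n_channels=profile.n_channels)
    volts = codes_to_volts(block.codes, profile)
    return volts.T.copy(), profile
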