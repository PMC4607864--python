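"""Signal reading/writing, framing conventions, and accelerometer-to-SPL calibration.

The ambulatory monitor records a single-channel neck-surface acceleration
signal (nominally 11 025 Hz).  The raw acceleration amplitude is in arbitrary
full-scale units; a daily calibration sequence — soft-to-loud vowels recorded
simultaneously on the accelerometer and on a microphone 15 cm from the lips —
yields a linear decibel-to-decibel regression that maps uncalibrated
acceleration frame levels to sound pressure level (dB SPL re 20 uPa at 15 cm).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Union

import numpy as np
from scipy.io import wavfile
from scipy.signal import butter, sosfilt

__all__ = [
    "RawSignal",
    "CalibrationMap",
    "FrameGrid",
    "SILENT",
    "read_signal",
    "write_signal",
    "frame_signal",
    "iter_frames",
    "frame_level_db",
    "frame_levels",
    "fit_spl_calibration",
    "apply_calibration",
    "highpass",
]

ChannelKind = Literal["acceleration", "microphone", "oral_airflow"]

#: Sentinel returned by :func:`frame_level_db` for frames whose RMS falls below
#: the silent floor.  It propagates through :func:`apply_calibration` as NaN.
SILENT = float("-inf")

#: Default RMS floor (full-scale units) below which a frame is "silent".
SILENT_RMS_FLOOR = 1e-6


@dataclass
class RawSignal:
    """A single-channel waveform with its sampling rate.

    Parameters
    ----------
    samples : ndarray
        Amplitude in arbitrary linear units (full scale [-1, 1] for PCM input).
    fs : float
        Sampling rate in Hz.
    channel_kind : str
        One of ``acceleration``, ``microphone``, ``oral_airflow``.
    """

    samples: np.ndarray
    fs: float
    channel_kind: ChannelKind = "acceleration"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError(f"expected 1-D samples, got shape {self.samples.shape}")
        if self.samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class CalibrationMap:
    """Affine dB-to-dB map from acceleration frame level to SPL at 15 cm."""

    slope: float
    intercept: float
    r: float
    ref_distance_cm: float = 15.0

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CalibrationMap":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class FrameGrid:
    """Frame layout over a signal: non-overlapping 50-ms frames by default."""

    frame_len_samples: int
    hop_samples: int
    n_frames: int
    frame_duration_s: float = 0.050

    def start(self, i: int) -> int:
        return i * self.hop_samples


def read_signal(path: Union[str, Path], channel_kind: ChannelKind = "acceleration") -> RawSignal:
    """Read a single-channel PCM or float WAV file into a :class:`RawSignal`.

    Integer PCM samples are scaled to [-1, 1] by the type's full-scale value.

    Raises
    ------
    ValueError
        If the file holds more than one channel (the channel count is named).
    """
    fs, data = wavfile.read(str(path))
    if data.ndim > 1:
        raise ValueError(
            f"expected a single-channel file, got {data.shape[1]} channels: {path}"
        )
    if data.size == 0:
        raise IOError(f"empty WAV file: {path}")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        scale = float(max(abs(info.min), info.max))
        samples = data.astype(float) / scale
    else:
        samples = data.astype(float)
    return RawSignal(samples=samples, fs=float(fs), channel_kind=channel_kind)


def write_signal(path: Union[str, Path], signal: RawSignal, subtype: str = "float") -> None:
    """Write a :class:`RawSignal` to WAV (``float`` or ``pcm16``)."""
    if subtype == "float":
        wavfile.write(str(path), int(round(signal.fs)), signal.samples.astype(np.float32))
    elif subtype == "pcm16":
        clipped = np.clip(signal.samples, -1.0, 1.0)
        wavfile.write(str(path), int(round(signal.fs)), np.round(clipped * 32767).astype(np.int16))
    else:
        raise ValueError(f"unknown subtype {subtype!r}")


def frame_signal(signal: RawSignal, frame_ms: float = 50.0, hop_ms: float | None = None) -> FrameGrid:
    """Lay a frame grid over a signal.

    Frame length is ``floor(fs * frame_ms)`` samples; trailing samples that do
    not fill a whole frame are dropped.  A signal shorter than one frame yields
    zero frames (not an error).
    """
    if frame_ms <= 0:
        raise ValueError("frame_ms must be positive")
    hop_ms = frame_ms if hop_ms is None else hop_ms
    if hop_ms <= 0:
        raise ValueError("hop_ms must be positive")
    frame_len = int(math.floor(signal.fs * frame_ms / 1000.0))
    hop = int(math.floor(signal.fs * hop_ms / 1000.0))
    n = len(signal)
    n_frames = (n - frame_len) // hop + 1 if n >= frame_len else 0
    return FrameGrid(
        frame_len_samples=frame_len,
        hop_samples=hop,
        n_frames=n_frames,
        frame_duration_s=frame_ms / 1000.0,
    )


def iter_frames(signal: RawSignal, grid: FrameGrid):
    """Yield ``(t_start_s, frame_samples)`` for every frame on the grid."""
    for i in range(grid.n_frames):
        s = grid.start(i)
        yield s / signal.fs, signal.samples[s : s + grid.frame_len_samples]


def frame_level_db(frame: np.ndarray, silent_floor: float = SILENT_RMS_FLOOR) -> float:
    """Uncalibrated acceleration level of one frame, in dB re 1.0 full scale.

    The frame mean is removed before the RMS (standing in for the monitor's
    0.9-Hz highpass), so the level is invariant to constant offsets.  Returns
    the :data:`SILENT` sentinel when the RMS falls below ``silent_floor``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    rms = float(np.sqrt(np.mean((frame - frame.mean()) ** 2)))
    if rms < silent_floor:
        return SILENT
    return 20.0 * math.log10(rms)


def frame_levels(signal: RawSignal, grid: FrameGrid, silent_floor: float = SILENT_RMS_FLOOR) -> np.ndarray:
    """Per-frame uncalibrated levels (dB); silent frames are ``-inf``."""
    return np.array([frame_level_db(f, silent_floor) for _, f in iter_frames(signal, grid)])


def fit_spl_calibration(acc_levels, mic_levels, ref_distance_cm: float = 15.0) -> CalibrationMap:
    """Ordinary least-squares fit of mic SPL on acceleration level (dB-dB plot).

    Mirrors the daily calibration sequence: soft-to-loud vowels measured as
    paired (acceleration level, microphone SPL) points.
    """
    acc = np.asarray(acc_levels, dtype=float)
    mic = np.asarray(mic_levels, dtype=float)
    if acc.shape != mic.shape or acc.ndim != 1:
        raise ValueError("acc_levels and mic_levels must be equal-length 1-D sequences")
    if acc.size < 2:
        raise ValueError("need at least two level pairs to fit a calibration line")
    if np.ptp(acc) == 0:
        raise ValueError("acceleration levels are all equal; calibration line is degenerate")
    slope, intercept = np.polyfit(acc, mic, 1)
    if np.ptp(mic) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(acc, mic)[0, 1])
    return CalibrationMap(slope=float(slope), intercept=float(intercept), r=r,
                          ref_distance_cm=ref_distance_cm)


def apply_calibration(level_db, cal: CalibrationMap):
    """Map uncalibrated acceleration level(s) in dB to dB SPL at the reference
    distance.  The silent sentinel (``-inf``) maps to NaN (SPL undefined; the
    frame is treated as unvoiced downstream)."""
    level = np.asarray(level_db, dtype=float)
    out = cal.slope * level + cal.intercept
    out = np.where(np.isneginf(level), np.nan, out)
    if np.isscalar(level_db) or level.ndim == 0:
        return float(out)
    return out


def highpass(signal: RawSignal, cutoff_hz: float = 0.9, order: int = 1) -> RawSignal:
    """First-order (by default) Butterworth highpass, emulating the recorder's
    high-fidelity 0.9-Hz analog highpass setting."""
    sos = butter(order, cutoff_hz, btype="highpass", fs=signal.fs, output="sos")
    return RawSignal(samples=sosfilt(sos, signal.samples), fs=signal.fs,
                     channel_kind=signal.channel_kind)
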