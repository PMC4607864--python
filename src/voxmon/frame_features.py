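"""Frame-based voice features from the neck-surface acceleration signal.

Eight features are computed per non-overlapping 50-ms frame: calibrated SPL,
fundamental frequency (f0), normalized autocorrelation peak amplitude,
subharmonic peak amplitude, harmonic spectral tilt, low-to-high spectral
ratio (split at 2 kHz), cepstral peak prominence (CPP), and zero crossing
rate.  A frame is labeled *voiced* when every computable feature falls inside
its configured range; the default ranges are the monitor's voicing criteria:

==========================  ==============
SPL                         45-130 dB SPL
f0                          70-1000 Hz
autocorrelation peak        0.60-1
subharmonic peak            0.25-1
harmonic tilt               -25-0 dB/oct
LH ratio                    22-50 dB
CPP                         10-35 dB
zero crossing rate          0-1
==========================  ==============
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import get_window

from .signal_io import (
    RawSignal,
    CalibrationMap,
    FrameGrid,
    frame_signal,
    iter_frames,
    frame_level_db,
    apply_calibration,
    SILENT,
)

__all__ = [
    "VoicingCriteria",
    "FrameFeatureRecord",
    "autocorr_f0",
    "subharmonic_peak",
    "harmonic_tilt",
    "lh_ratio",
    "cpp",
    "zcr",
    "classify_voicing",
    "extract_features",
    "records_to_frame",
]

SubharmonicMode = Literal["correct", "reject", "ignore"]


@dataclass
class VoicingCriteria:
    """Per-feature [min, max] ranges for a frame to be considered voiced."""

    spl: tuple = (45.0, 130.0)
    f0: tuple = (70.0, 1000.0)
    ac_peak: tuple = (0.60, 1.0)
    subharmonic: tuple = (0.25, 1.0)
    tilt: tuple = (-25.0, 0.0)
    lh_ratio: tuple = (22.0, 50.0)
    cpp: tuple = (10.0, 35.0)
    zcr: tuple = (0.0, 1.0)
    #: how a subharmonic peak inside its range is handled: ``correct`` halves
    #: f0 (octave correction), ``reject`` marks the frame unvoiced, ``ignore``
    #: leaves the frame untouched.
    subharmonic_mode: SubharmonicMode = "correct"

    def __post_init__(self) -> None:
        for name in ("spl", "f0", "ac_peak", "subharmonic", "tilt", "lh_ratio", "cpp", "zcr"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"criterion {name}: min {lo} > max {hi}")

    def in_range(self, name: str, value: Optional[float]) -> bool:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return True  # absent features do not veto; absent f0 handled separately
        lo, hi = getattr(self, name)
        return lo <= value <= hi


@dataclass
class FrameFeatureRecord:
    """Feature values for one 50-ms frame.  Absent features are NaN."""

    t_start: float
    spl: float = math.nan
    f0: float = math.nan
    ac_peak: float = math.nan
    subharmonic: float = math.nan
    tilt: float = math.nan
    lh_ratio: float = math.nan
    cpp: float = math.nan
    zcr: float = math.nan
    voiced: bool = False


def _spectrum_nfft(frame_len: int) -> int:
    # next power of two >= 4x frame length: stable harmonic peak picking
    return 1 << int(math.ceil(math.log2(4 * frame_len)))


def _normalized_autocorr(frame: np.ndarray) -> np.ndarray:
    """Unbiased normalized autocorrelation (lag-0 value 1; the (N-l)/N
    shrinkage of the raw estimator is divided out so a pure tone's period
    peak reaches ~1 regardless of frame length)."""
    x = frame - frame.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return np.zeros(len(x))
    n = len(x)
    nfft = 1 << int(math.ceil(math.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    ac = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    lags = np.arange(n)
    ac = ac * (n / (n - lags))
    return ac / denom


def _parabolic_refine(y: np.ndarray, k: int):
    """Parabolic interpolation of a local maximum at index k; returns
    (refined position, refined value)."""
    if k <= 0 or k >= len(y) - 1:
        return float(k), float(y[k])
    a, b, c = y[k - 1], y[k], y[k + 1]
    denom = a - 2 * b + c
    if denom == 0:
        return float(k), float(b)
    delta = 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    return k + delta, float(b - 0.25 * (a - c) * delta)


def autocorr_f0(frame: np.ndarray, fs: float, f_range=(70.0, 1000.0)):
    """Fundamental frequency from the normalized autocorrelation function.

    f0 is the reciprocal of the lag of the first local maximum within the
    search band ``[fs/f_max, fs/f_min]``; the peak amplitude is refined by
    parabolic interpolation.  Returns ``(f0, ac_peak, peak_lag)``; f0 is NaN
    when no local maximum exists in the band (ties favour the smaller lag,
    i.e. the higher f0, because the *first* peak is taken).
    """
    f_min, f_max = f_range
    frame = np.asarray(frame, dtype=float)
    lag_min = int(math.floor(fs / f_max))
    lag_max = int(math.ceil(fs / f_min))
    if lag_min < 1:
        lag_min = 1
    if len(frame) < lag_max + 2:
        return math.nan, math.nan, math.nan  # frame too short for the lowest f0
    ac = _normalized_autocorr(frame)
    seg = ac[lag_min : lag_max + 1]
    # local maxima within the band
    interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return math.nan, math.nan, math.nan
    # first local maximum that is also the dominant peak candidate: take the
    # earliest local max whose height is within 80% of the band maximum, so a
    # tiny ripple before the true period peak is not mistaken for it.
    band_max = float(seg[idx].max())
    for k in idx:
        if seg[k] >= 0.8 * band_max:
            lag0 = lag_min + int(k)
            lag_ref, peak_val = _parabolic_refine(ac, lag0)
            return fs / lag_ref, min(peak_val, 1.0), lag_ref
    return math.nan, math.nan, math.nan


def subharmonic_peak(ac: np.ndarray, peak_lag: float, tolerance: float = 0.15) -> float:
    """Amplitude of a secondary autocorrelation peak located around half way
    to the main peak.

    A period-2 alternation (e.g. diplophonia) puts the main autocorrelation
    peak at the doubled period and a secondary peak half way to it.  The
    search window is ``peak_lag/2 * (1 +/- tolerance)``.  Returns NaN when no
    local maximum exists there.
    """
    if not np.isfinite(peak_lag):
        return math.nan
    lo = int(math.floor(peak_lag / 2 * (1 - tolerance)))
    hi = int(math.ceil(peak_lag / 2 * (1 + tolerance)))
    lo = max(lo, 1)
    hi = min(hi, len(ac) - 2)
    if hi <= lo:
        return math.nan
    seg = ac[lo : hi + 1]
    interior = (seg[1:-1] > seg[:-2]) & (seg[1:-1] >= seg[2:])
    idx = np.nonzero(interior)[0] + 1
    if idx.size == 0:
        return math.nan
    k = idx[np.argmax(seg[idx])]
    _, val = _parabolic_refine(ac, lo + int(k))
    return val


def harmonic_tilt(frame: np.ndarray, fs: float, f0: float, n_harm: int = 8) -> float:
    """Spectral tilt in dB/octave: OLS slope of harmonic amplitude (dB) on
    log2(frequency) over the first ``n_harm`` harmonics.

    Harmonic amplitude is the spectral maximum within +/- f0/4 of each ideal
    harmonic frequency.  NaN when fewer than 3 harmonics fit below Nyquist.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.isfinite(f0) or f0 <= 0:
        return math.nan
    nyq = fs / 2
    k_max = min(n_harm, int(nyq / f0))
    if k_max < 3:
        return math.nan
    x = frame - frame.mean()
    nfft = _spectrum_nfft(len(x))
    mag = np.abs(np.fft.rfft(x * get_window("hann", len(x)), nfft))
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    amps_db, log2f = [], []
    for k in range(1, k_max + 1):
        f_k = k * f0
        band = (freqs >= f_k - f0 / 4) & (freqs <= f_k + f0 / 4)
        if not band.any():
            continue
        a = float(mag[band].max())
        if a <= 0:
            continue
        j = np.nonzero(band)[0][np.argmax(mag[band])]
        amps_db.append(20 * math.log10(a))
        log2f.append(math.log2(freqs[j] if freqs[j] > 0 else f_k))
    if amps_db:
        # drop "harmonics" that are numerically absent (e.g. a pure tone's
        # k >= 2 bins, which only sample the transform's noise floor)
        top = max(amps_db)
        keep = [i for i, a in enumerate(amps_db) if a >= top - 80.0]
        amps_db = [amps_db[i] for i in keep]
        log2f = [log2f[i] for i in keep]
    if len(amps_db) < 3:
        return math.nan
    slope = np.polyfit(log2f, amps_db, 1)[0]
    return float(slope)


def lh_ratio(frame: np.ndarray, fs: float, split_hz: float = 2000.0,
             floor: float = 1e-12) -> float:
    """Low-to-high spectral power ratio in dB, split at ``split_hz``.

    The high-band power is floored at ``floor`` times the total power so the
    ratio stays finite for signals with no high-frequency content.
    """
    frame = np.asarray(frame, dtype=float)
    x = frame - frame.mean()
    nfft = _spectrum_nfft(len(x))
    p = np.abs(np.fft.rfft(x * get_window("hann", len(x)), nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1 / fs)
    p_low = float(p[freqs < split_hz].sum())
    p_high = float(p[freqs >= split_hz].sum())
    total = p_low + p_high
    if total == 0:
        return 0.0
    p_high = max(p_high, floor * total)
    p_low = max(p_low, floor * total)
    return 10 * math.log10(p_low / p_high)


def cpp(frame: np.ndarray, fs: float, f_range=(70.0, 1000.0)) -> float:
    """Cepstral peak prominence in dB.

    The power cepstrum is the squared magnitude of the inverse transform of
    the dB power spectrum of the Hann-windowed frame, itself expressed in
    dB.  The peak is searched over quefrencies [1/f_max, 1/f_min] and
    referenced to an OLS regression line of the dB cepstrum over that
    range.  Being baseline-relative makes the measure invariant to overall
    signal scale (a spectrum-level offset moves only the zero-quefrency
    bin).
    """
    frame = np.asarray(frame, dtype=float)
    f_min, f_max = f_range
    x = frame - frame.mean()
    if not np.any(x):
        return 0.0
    nfft = _spectrum_nfft(len(x))
    spec = np.abs(np.fft.rfft(x * get_window("hann", len(x)), nfft))
    log_power = 20 * np.log10(np.maximum(spec, 1e-150))
    ceps = np.fft.irfft(log_power)          # quefrency in samples (q / fs s)
    # smooth the power cepstrum before the dB transform: the log of a
    # near-zero cepstral bin otherwise drags the regression baseline down
    # and inflates the peak of aperiodic frames
    power = ceps**2
    win = 5
    kernel = np.ones(win) / win
    smoothed = np.convolve(power, kernel, mode="same")
    ceps_db = 10 * np.log10(np.maximum(smoothed, 1e-300))
    q_min = int(math.floor(fs / f_max))
    q_max = int(math.ceil(fs / f_min))
    q_max = min(q_max, len(ceps) // 2)
    if q_max <= q_min + 2:
        return math.nan
    quef = np.arange(q_min, q_max + 1)
    seg = ceps_db[q_min : q_max + 1]
    k = int(np.argmax(seg))
    base = np.polyval(np.polyfit(quef, seg, 1), quef[k])
    return float(seg[k] - base)


def zcr(frame: np.ndarray) -> float:
    """Proportion of the frame over which the signal crosses its mean:
    sign changes of the mean-removed samples divided by the frame length."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame must be non-empty")
    x = frame - frame.mean()
    s = np.sign(x)
    s[s == 0] = 1
    return float(np.count_nonzero(s[1:] != s[:-1]) / frame.size)


def classify_voicing(record: FrameFeatureRecord, criteria: VoicingCriteria) -> bool:
    """Voicing decision: pure conjunction of the per-feature range criteria.

    Absent (NaN) features pass; absent f0 fails outright.  A subharmonic peak
    inside its range is handled per ``criteria.subharmonic_mode`` — by default
    it triggers octave correction in :func:`extract_features`, not rejection.
    """
    if not np.isfinite(record.f0):
        return False
    checks = [
        criteria.in_range("spl", record.spl),
        criteria.in_range("f0", record.f0),
        criteria.in_range("ac_peak", record.ac_peak),
        criteria.in_range("tilt", record.tilt),
        criteria.in_range("lh_ratio", record.lh_ratio),
        criteria.in_range("cpp", record.cpp),
        criteria.in_range("zcr", record.zcr),
    ]
    if criteria.subharmonic_mode == "reject" and np.isfinite(record.subharmonic):
        lo, hi = criteria.subharmonic
        if lo <= record.subharmonic <= hi:
            return False
    return all(checks)


def extract_features(
    signal: RawSignal,
    cal: CalibrationMap,
    criteria: VoicingCriteria | None = None,
    frame_ms: float = 50.0,
) -> list[FrameFeatureRecord]:
    """Compute the full per-frame feature set over the non-overlapping grid.

    SPL is computed from the mean-removed frame RMS through the calibration
    map before any spectral windowing.  With ``subharmonic_mode='correct'``
    (default), a subharmonic peak inside its criterion range halves f0
    (octave correction) instead of rejecting the frame.
    """
    criteria = criteria or VoicingCriteria()
    grid = frame_signal(signal, frame_ms=frame_ms)
    records: list[FrameFeatureRecord] = []
    for t, frame in iter_frames(signal, grid):
        rec = FrameFeatureRecord(t_start=t)
        level = frame_level_db(frame)
        rec.spl = apply_calibration(level, cal) if level != SILENT else math.nan
        f0, ac_peak, peak_lag = autocorr_f0(frame, signal.fs, criteria.f0)
        rec.f0, rec.ac_peak = f0, ac_peak
        if np.isfinite(peak_lag):
            ac = _normalized_autocorr(frame)
            rec.subharmonic = subharmonic_peak(ac, peak_lag)
            if (
                criteria.subharmonic_mode == "correct"
                and np.isfinite(rec.subharmonic)
                and criteria.subharmonic[0] <= rec.subharmonic <= criteria.subharmonic[1]
            ):
                # the "secondary" peak marks the true (doubled) period
                rec.f0 = f0 / 2 if f0 / 2 >= criteria.f0[0] else f0
        if np.isfinite(rec.f0):
            rec.tilt = harmonic_tilt(frame, signal.fs, rec.f0)
        rec.lh_ratio = lh_ratio(frame, signal.fs)
        rec.cpp = cpp(frame, signal.fs, criteria.f0)
        rec.zcr = zcr(frame)
        rec.voiced = classify_voicing(rec, criteria)
        records.append(rec)
    return records


def records_to_frame(records: Sequence[FrameFeatureRecord]):
    """Per-frame records as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([asdict(r) for r in records])
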