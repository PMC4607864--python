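"""Accumulated vocal doses and voiced/unvoiced segment structure.

Three dose measures quantify accumulated daily voice use:

* **phonation time** — cumulative duration of vocal fold vibration, also as a
  percentage of monitored time;
* **cycle dose** — estimated number of vocal fold oscillations,
  ``sum(f0 * frame_duration)`` over voiced frames;
* **distance dose** — estimated total distance traveled by the vibrating
  folds, ``sum(4 * A(SPL) * f0 * frame_duration)``, where the vibratory
  amplitude A grows exponentially with SPL.

Contiguous voiced/unvoiced runs summarize vocal load and recovery; merging
short unvoiced gaps (< 0.5 s by default) approximates breath-group phrases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .frame_features import FrameFeatureRecord

__all__ = [
    "DoseSummary",
    "SegmentSeries",
    "AmplitudeRule",
    "phonation_time",
    "cycle_dose",
    "distance_dose",
    "dose_summary",
    "run_segments",
    "merge_phrases",
    "segment_histograms",
    "voiced_unvoiced_pair_histogram",
    "default_duration_bins",
]

FRAME_S = 0.050


@dataclass
class AmplitudeRule:
    """Vocal-fold vibratory amplitude (meters) as a function of SPL:
    ``A = a0 * 10**((spl - p0) / s)``.

    Defaults follow the vocal-dose literature's amplitude scaling: roughly
    1 mm at 90 dB SPL, doubling every ~12 dB.
    """

    a0: float = 1e-3
    p0: float = 90.0
    s: float = 40.0

    def __call__(self, spl: float) -> float:
        a = self.a0 * 10 ** ((spl - self.p0) / self.s)
        if a < 0:
            raise ValueError("amplitude rule produced a negative amplitude")
        return a


@dataclass
class DoseSummary:
    monitoring_time_s: float
    phonation_time_s: float
    phonation_pct: float
    cycle_dose: float
    cycle_dose_per_h: float
    distance_dose_m: float
    distance_dose_per_h: float


@dataclass
class SegmentSeries:
    """Alternating (state, duration) runs of the voicing decision sequence."""

    runs: list  # [(state: 'voiced'|'unvoiced', duration_s)]
    frame_duration_s: float = FRAME_S
    gap_threshold_s: float = 0.5

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.runs))

    def voiced_durations(self) -> np.ndarray:
        return np.array([d for s, d in self.runs if s == "voiced"])

    def unvoiced_durations(self) -> np.ndarray:
        return np.array([d for s, d in self.runs if s == "unvoiced"])


def _voiced_mask(frames: Sequence[FrameFeatureRecord], mask=None) -> np.ndarray:
    v = np.array([f.voiced for f in frames], dtype=bool)
    if mask is not None:
        keep = np.asarray(mask, dtype=bool)
        v = v[keep]
    return v


def phonation_time(frames: Sequence[FrameFeatureRecord], frame_s: float = FRAME_S,
                   mask=None):
    """Cumulative voiced time in seconds and as percent of monitored frames.

    ``mask`` optionally marks frames that count as monitored (False = device
    paused); paused frames are excluded from both numerator and denominator.
    """
    if len(frames) == 0:
        raise ValueError("no frames")
    v = _voiced_mask(frames, mask)
    if v.size == 0:
        return 0.0, 0.0
    seconds = float(v.sum()) * frame_s
    return seconds, 100.0 * float(v.sum()) / v.size


def cycle_dose(frames: Sequence[FrameFeatureRecord], frame_s: float = FRAME_S,
               mask=None) -> float:
    """Estimated number of vocal-fold oscillation cycles."""
    total = 0.0
    keep = np.ones(len(frames), bool) if mask is None else np.asarray(mask, bool)
    for f, k in zip(frames, keep):
        if not k or not f.voiced:
            continue
        if not np.isfinite(f.f0):
            raise ValueError("voiced frame with absent f0")
        total += f.f0 * frame_s
    return total


def distance_dose(frames: Sequence[FrameFeatureRecord],
                  amp_rule: Optional[AmplitudeRule] = None,
                  frame_s: float = FRAME_S, mask=None) -> float:
    """Estimated total vocal-fold travel distance in meters.

    Each voiced frame contributes ``4 * A(SPL) * f0 * frame_duration`` — four
    amplitude traversals per oscillation cycle.
    """
    amp_rule = amp_rule or AmplitudeRule()
    total = 0.0
    keep = np.ones(len(frames), bool) if mask is None else np.asarray(mask, bool)
    for f, k in zip(frames, keep):
        if not k or not f.voiced:
            continue
        if not np.isfinite(f.f0):
            raise ValueError("voiced frame with absent f0")
        total += 4.0 * amp_rule(f.spl) * f.f0 * frame_s
    return total


def dose_summary(frames: Sequence[FrameFeatureRecord],
                 amp_rule: Optional[AmplitudeRule] = None,
                 frame_s: float = FRAME_S, mask=None) -> DoseSummary:
    keep = np.ones(len(frames), bool) if mask is None else np.asarray(mask, bool)
    monitored_s = float(keep.sum()) * frame_s
    hours = monitored_s / 3600.0
    sec, pct = phonation_time(frames, frame_s, mask)
    cd = cycle_dose(frames, frame_s, mask)
    dd = distance_dose(frames, amp_rule, frame_s, mask)
    return DoseSummary(
        monitoring_time_s=monitored_s,
        phonation_time_s=sec,
        phonation_pct=pct,
        cycle_dose=cd,
        cycle_dose_per_h=cd / hours if hours > 0 else 0.0,
        distance_dose_m=dd,
        distance_dose_per_h=dd / hours if hours > 0 else 0.0,
    )


def run_segments(frames: Sequence[FrameFeatureRecord],
                 frame_s: float = FRAME_S) -> SegmentSeries:
    """Run-length encode the voicing decision sequence into maximal
    same-state segments."""
    v = _voiced_mask(frames)
    runs = []
    if v.size:
        change = np.nonzero(np.diff(v))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [v.size]])
        for s, e in zip(starts, ends):
            runs.append(("voiced" if v[s] else "unvoiced", (e - s) * frame_s))
    return SegmentSeries(runs=runs, frame_duration_s=frame_s)


def merge_phrases(series: SegmentSeries, gap_threshold_s: float = 0.5) -> SegmentSeries:
    """Absorb unvoiced gaps strictly shorter than the threshold into the
    surrounding voiced runs; the merged voiced runs approximate speech
    phrases produced on single breaths.

    Leading/trailing unvoiced runs are kept regardless of duration (they have
    no surrounding voiced run on both sides).  Total duration is conserved.
    """
    runs = list(series.runs)
    merged: list = []
    for i, (state, dur) in enumerate(runs):
        absorb = (
            state == "unvoiced"
            and 0 < i < len(runs) - 1
            and dur < gap_threshold_s
        )
        if absorb:
            state = "voiced"
        if merged and merged[-1][0] == state:
            merged[-1] = (state, merged[-1][1] + dur)
        else:
            merged.append((state, dur))
    return SegmentSeries(runs=merged, frame_duration_s=series.frame_duration_s,
                         gap_threshold_s=gap_threshold_s)


def default_duration_bins(frame_s: float = FRAME_S) -> np.ndarray:
    """Logarithmic duration bin edges from one frame (50 ms) up to 300 s."""
    return np.geomspace(frame_s, 300.0, 41)


def segment_histograms(series: SegmentSeries, state: str = "voiced",
                       bins: Optional[np.ndarray] = None):
    """Occurrence and accumulation histograms of run durations.

    Returns ``(bin_edges, counts, accumulated_seconds)``: counts of runs per
    duration bin and total time spent in runs of each bin.
    """
    if bins is None:
        bins = default_duration_bins(series.frame_duration_s)
    durs = series.voiced_durations() if state == "voiced" else series.unvoiced_durations()
    counts, edges = np.histogram(durs, bins=bins)
    acc = np.zeros_like(counts, dtype=float)
    idx = np.clip(np.digitize(durs, edges) - 1, 0, len(counts) - 1)
    for i, d in zip(idx, durs):
        acc[i] += d
    return edges, counts, acc


def voiced_unvoiced_pair_histogram(series: SegmentSeries,
                                   monitored_hours: float,
                                   bins: Optional[np.ndarray] = None):
    """2-D occurrence histogram (per hour) of (voiced duration, immediately
    following unvoiced duration) pairs — how much voice rest follows bursts
    of voicing activity.  A trailing voiced run with no following unvoiced
    run contributes to no bin."""
    if monitored_hours <= 0:
        raise ValueError("monitored_hours must be positive")
    if bins is None:
        bins = default_duration_bins(series.frame_duration_s)
    v_durs, u_durs = [], []
    runs = series.runs
    for i in range(len(runs) - 1):
        if runs[i][0] == "voiced" and runs[i + 1][0] == "unvoiced":
            v_durs.append(runs[i][1])
            u_durs.append(runs[i + 1][1])
    hist, xe, ye = np.histogram2d(v_durs, u_durs, bins=[bins, bins])
    return xe, ye, hist / monitored_hours
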