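"""Synthetic data: glottal pulse trains, forward-modeled acceleration signals,
day-long frame streams, and paired cohorts with injected group effects.

Every generator is deterministic under a fixed seed and emits ground truth
alongside the signal, so each pipeline stage can be tested without real
recordings:

* :func:`synth_glottal_flow` — a piecewise-linear (or raised-cosine) glottal
  pulse train whose per-cycle OQ, SQ, AC Flow, MFDR and NAQ have closed forms;
* :func:`synth_acc_signal` — neck-surface acceleration via the forward
  transmission-line model plus calibrated broadband noise;
* :func:`synth_day_frames` — frame-feature streams drawn from prescribed
  voiced-fraction / SPL / f0 distributions, for dose and window analyses;
* :func:`synth_cohort` — paired patient/control window-feature tables with
  prescribed shifts (in baseline-SD units) of the normalized statistics,
  mimicking the right-shifted SPL/f0 distributions seen in phonotrauma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .signal_io import RawSignal
from .frame_features import FrameFeatureRecord
from .ibif import SubglottalModel, forward_simulate

__all__ = [
    "VoiceSpec",
    "CohortSpec",
    "CycleTruth",
    "synth_glottal_flow",
    "synth_acc_signal",
    "DayPlan",
    "HourPlan",
    "normal_sampler",
    "lognormal_sampler",
    "synth_day_frames",
    "synth_cohort",
    "FEATURE_COLUMNS",
]

PulseShape = Literal["triangular", "cosine"]


@dataclass
class VoiceSpec:
    """Prescription for a synthetic voiced signal.

    ``open_fraction`` is the per-cycle OQ by construction; ``speed_ratio`` is
    the rise/fall time ratio, so SQ = 100*speed_ratio.
    """

    f0_hz: float = 200.0
    duration_s: float = 1.0
    amplitude: float = 1.0
    open_fraction: float = 0.6
    speed_ratio: float = 1.0
    shape: PulseShape = "triangular"
    noise_snr_db: float = math.inf
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.open_fraction < 1:
            raise ValueError("open_fraction must lie in (0, 1)")
        if self.speed_ratio <= 0:
            raise ValueError("speed_ratio must be positive")


@dataclass
class CycleTruth:
    """Closed-form per-cycle ground truth for the synthetic pulse train."""

    t_start: float
    period_s: float
    ac_flow: float
    mfdr: float
    oq: float
    sq: float
    naq: float


def _pulse_value(tau: np.ndarray, amp: float, t_op: float, t_cp: float,
                 shape: PulseShape) -> np.ndarray:
    """Flow value within one cycle at time tau since cycle start (open phase
    first: rise over t_op, fall over t_cp, then closed)."""
    t_o = t_op + t_cp
    out = np.zeros_like(tau)
    rising = (tau >= 0) & (tau < t_op)
    falling = (tau >= t_op) & (tau < t_o)
    if shape == "triangular":
        out[rising] = amp * tau[rising] / t_op
        out[falling] = amp * (t_o - tau[falling]) / t_cp
    else:  # raised cosine
        out[rising] = amp * 0.5 * (1 - np.cos(np.pi * tau[rising] / t_op))
        out[falling] = amp * 0.5 * (1 + np.cos(np.pi * (tau[falling] - t_op) / t_cp))
    return out


def synth_glottal_flow(spec: VoiceSpec, fs: float = 11025.0):
    """Generate a glottal pulse train and its ground-truth cycle table.

    Cycle start times accumulate continuous periods (not sample-aligned);
    closed forms: AC = amplitude, MFDR = AC/t_cp (triangular) or
    pi*AC/(2*t_cp) (cosine), OQ = open_fraction, SQ = 100*speed_ratio,
    NAQ = (AC/MFDR)/T.

    Returns ``(RawSignal, list[CycleTruth])``.
    """
    if 8 * spec.f0_hz > fs / 2:
        import warnings

        warnings.warn("fewer than 8 harmonics fit below Nyquist; harmonic truncation")
    n = int(round(spec.duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    truths: list[CycleTruth] = []
    t0 = 0.0
    period = 1.0 / spec.f0_hz
    while t0 + period <= spec.duration_s + 1e-12:
        t_o = spec.open_fraction * period
        t_op = t_o * spec.speed_ratio / (1 + spec.speed_ratio)
        t_cp = t_o / (1 + spec.speed_ratio)
        sel = (t >= t0) & (t < t0 + period)
        x[sel] += _pulse_value(t[sel] - t0, spec.amplitude, t_op, t_cp, spec.shape)
        if spec.shape == "triangular":
            mfdr = spec.amplitude / t_cp
        else:
            mfdr = math.pi * spec.amplitude / (2 * t_cp)
        truths.append(CycleTruth(
            t_start=t0, period_s=period, ac_flow=spec.amplitude, mfdr=mfdr,
            oq=spec.open_fraction, sq=100.0 * spec.speed_ratio,
            naq=(spec.amplitude / mfdr) / period,
        ))
        t0 += period
    if math.isfinite(spec.noise_snr_db):
        rng = np.random.default_rng(spec.seed)
        x = _add_noise(x, spec.noise_snr_db, rng)
    return RawSignal(x, fs, "oral_airflow"), truths


def _add_noise(x: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    sig_power = float(np.mean((x - x.mean()) ** 2))
    noise = rng.standard_normal(len(x))
    noise -= noise.mean()
    target = sig_power / 10 ** (snr_db / 10)
    noise *= math.sqrt(target / np.mean(noise**2))
    return x + noise


def synth_acc_signal(flow: RawSignal, model: SubglottalModel,
                     noise_snr_db: float = math.inf, seed: int = 0) -> RawSignal:
    """Forward-simulate neck-surface acceleration and add seeded broadband
    noise scaled to exactly the stated SNR."""
    acc = forward_simulate(flow, model)
    if math.isinf(noise_snr_db):
        return acc
    rng = np.random.default_rng(seed)
    return RawSignal(_add_noise(acc.samples, noise_snr_db, rng), acc.fs,
                     "acceleration")


#: (f0 Hz, relative amplitude) of the daily calibration vowels
CALIBRATION_VOWELS = ((180.0, 0.3), (200.0, 1.0), (215.0, 2.5))


def synth_calibration_vowels(model: SubglottalModel, duration_s: float = 3.0,
                             noise_snr_db: float = math.inf, seed: int = 0,
                             vowels=CALIBRATION_VOWELS, fs: float = 11025.0):
    """Soft/comfortable/loud sustained-vowel pairs for Q calibration.

    Returns ``(acc_list, flow_list)``: acceleration forward-simulated through
    ``model`` (with seeded noise) and the corresponding true glottal flows.
    """
    accs, flows = [], []
    for i, (f0, amp) in enumerate(vowels):
        spec = VoiceSpec(f0_hz=f0, duration_s=duration_s, amplitude=amp,
                         open_fraction=0.6, speed_ratio=2.0)
        flow, _ = synth_glottal_flow(spec, fs)
        accs.append(synth_acc_signal(flow, model, noise_snr_db, seed + 17 * i))
        flows.append(flow)
    return accs, flows


# ----------------------------------------------------------------------------
# frame-level day streams
# ----------------------------------------------------------------------------

Sampler = Callable[[np.random.Generator, int], np.ndarray]


def normal_sampler(mean: float, sd: float) -> Sampler:
    return lambda rng, size: rng.normal(mean, sd, size)


def lognormal_sampler(offset: float, mu: float, sigma: float) -> Sampler:
    """``offset + LogNormal(mu, sigma)``; skewness has the closed form
    (exp(sigma^2)+2) * sqrt(exp(sigma^2)-1)."""
    return lambda rng, size: offset + rng.lognormal(mu, sigma, size)


@dataclass
class HourPlan:
    """One block of a synthetic day: voiced fraction and the voiced-frame
    SPL/f0 distributions."""

    duration_s: float = 3600.0
    voiced_fraction: float = 0.10
    spl: Sampler = field(default_factory=lambda: normal_sampler(84.0, 8.0))
    f0: Sampler = field(default_factory=lambda: normal_sampler(200.0, 30.0))


@dataclass
class DayPlan:
    hours: Sequence[HourPlan]
    frame_s: float = 0.050
    seed: int = 0


def synth_day_frames(plan: DayPlan) -> list[FrameFeatureRecord]:
    """Draw a frame-feature stream from the day plan's distributions.

    Voicing flags are Bernoulli draws at each hour's voiced fraction; voiced
    frames carry SPL/f0 from the stated samplers (f0 clipped to 70-1000 Hz,
    SPL to 45-130 dB so records honour the voicing-criteria invariant);
    unvoiced frames have absent features.
    """
    rng = np.random.default_rng(plan.seed)
    records: list[FrameFeatureRecord] = []
    t = 0.0
    for hour in plan.hours:
        n = int(round(hour.duration_s / plan.frame_s))
        voiced = rng.random(n) < hour.voiced_fraction
        spl = np.clip(hour.spl(rng, n), 45.0, 130.0)
        f0 = np.clip(hour.f0(rng, n), 70.0, 1000.0)
        for i in range(n):
            if voiced[i]:
                records.append(FrameFeatureRecord(
                    t_start=t, spl=float(spl[i]), f0=float(f0[i]),
                    ac_peak=0.85, tilt=-14.0, lh_ratio=30.0, cpp=22.0,
                    zcr=0.04, voiced=True))
            else:
                records.append(FrameFeatureRecord(t_start=t, voiced=False))
            t += plan.frame_s
    return records


# ----------------------------------------------------------------------------
# paired cohorts of window features
# ----------------------------------------------------------------------------

_STATS = ("mean", "sd", "skew", "kurtosis", "p5", "p95")
FEATURE_COLUMNS = (
    [f"spl_{s}" for s in _STATS]
    + [f"f0_{s}" for s in _STATS]
    + ["percent_phonation"]
    + [f"norm_spl_{s}" for s in _STATS]
    + [f"norm_f0_{s}" for s in _STATS]
    + ["norm_percent_phonation"]
)

# plausible raw window-statistic centres (location, scale) for an adult female
_RAW_BASE = {
    "spl_mean": (84.0, 3.0), "spl_sd": (7.0, 1.0), "spl_skew": (0.0, 0.4),
    "spl_kurtosis": (3.0, 0.5), "spl_p5": (72.0, 3.0), "spl_p95": (96.0, 3.0),
    "f0_mean": (200.0, 15.0), "f0_sd": (30.0, 5.0), "f0_skew": (0.0, 0.4),
    "f0_kurtosis": (3.0, 0.5), "f0_p5": (155.0, 12.0), "f0_p95": (260.0, 20.0),
    "percent_phonation": (10.0, 3.0),
}


@dataclass
class CohortSpec:
    """Paired-cohort prescription.

    ``effect`` maps feature column names to the patient-group mean shift in
    units of the window-to-window SD.  The default right-shifts the
    normalized SPL skew and normalized f0 95th percentile, the directionality
    characteristic of phonotraumatic vocal hyperfunction.
    """

    n_pairs: int = 20
    windows_per_subject: int = 50
    effect: dict = field(default_factory=lambda: {
        "norm_spl_skew": 1.5, "norm_f0_p95": 1.5})
    subject_sd: float = 0.3   # between-subject random offset, in window-SD units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("need at least 2 pairs")
        for k, v in self.effect.items():
            if not math.isfinite(v):
                raise ValueError(f"effect for {k} must be finite")


def synth_cohort(spec: CohortSpec):
    """Generate a paired cohort's manifest and window feature table.

    Returns ``(manifest, features)`` DataFrames.  The manifest has columns
    ``subject_id, pair_id, group``; the feature table one row per window with
    ``subject_id`` plus every column in :data:`FEATURE_COLUMNS` and the
    binary ``label`` (1 = patient).  Normalized statistics are drawn as
    N(shift, 1) for patients and N(0, 1) for controls (plus a between-subject
    offset); raw statistics are drawn around plausible ambulatory values.
    """
    rng = np.random.default_rng(spec.seed)
    manifest_rows, feat_rows = [], []
    for p in range(spec.n_pairs):
        for group, label in (("patient", 1), ("control", 0)):
            sid = f"P{p:03d}_{group}"
            manifest_rows.append({"subject_id": sid, "pair_id": p, "group": group})
            subj_offset = {c: rng.normal(0, spec.subject_sd) for c in FEATURE_COLUMNS}
            for w in range(spec.windows_per_subject):
                row = {"subject_id": sid, "pair_id": p, "label": label,
                       "window_index": w}
                for c in FEATURE_COLUMNS:
                    if c in _RAW_BASE:
                        loc, scale = _RAW_BASE[c]
                        val = loc + scale * (subj_offset[c] + rng.standard_normal())
                        shift = spec.effect.get(c, 0.0) * label
                        row[c] = val + shift * scale
                    else:
                        shift = spec.effect.get(c, 0.0) * label
                        row[c] = shift + subj_offset[c] + rng.standard_normal()
                feat_rows.append(row)
    return pd.DataFrame(manifest_rows), pd.DataFrame(feat_rows)
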