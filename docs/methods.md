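# Methods

`voxmon` analyzes single-channel neck-surface acceleration recordings of the
kind produced by ambulatory voice monitors: a miniature accelerometer taped to
the neck below the larynx, sampled at 11 025 Hz, capturing a voice-related
signal that is immune to ambient sound and carries no intelligible speech.
This note documents the models, the parameters that matter, the numerical
choices, and what the synthetic-data tests do and do not establish.

## Calibration and frame features

The raw acceleration amplitude is in arbitrary full-scale units.  A daily
calibration sequence — vowels produced from soft to loud, recorded
simultaneously on the accelerometer and on a microphone 15 cm from the lips —
yields paired (acceleration level, microphone SPL) points in dB; an ordinary
least-squares line on this dB–dB plot maps uncalibrated frame levels to
dB SPL re 20 µPa at 15 cm.  The absolute acceleration reference is irrelevant
because the affine map absorbs it.

Eight features are computed per non-overlapping 50-ms frame (551 samples at
11 025 Hz; trailing partial frames are dropped).  Frame means are removed
before everything, standing in for the recorder's 0.9-Hz analog highpass; an
optional first-order Butterworth highpass is available for full-signal
preprocessing.

* **SPL** — calibrated dB of the frame RMS.  Frames with RMS below 10⁻⁶ full
  scale are "silent" and propagate as unvoiced.
* **f0 and autocorrelation peak** — the first local maximum of the unbiased
  normalized autocorrelation within lags [fs/1000, fs/70], refined by
  parabolic interpolation (ties break to the smaller lag, i.e. the higher
  f0).  The raw estimator's (N−l)/N shrinkage is divided out so a pure
  tone's peak reads ~1 at any frame length.  A small ripple ahead of the
  true period peak is skipped by requiring the chosen peak to reach 80% of
  the in-band maximum.
* **Subharmonic peak** — the largest autocorrelation local maximum within
  ±15% of half the f0 lag.  A period-2 alternation (e.g. diplophonia) puts
  the main peak at the doubled period; when a subharmonic peak in
  [0.25, 1] exists, the default policy (`subharmonic_mode="correct"`)
  halves f0 (octave correction) rather than rejecting the frame, so clearly
  periodic frames stay voiced.  `reject` and `ignore` modes are available.
* **Harmonic spectral tilt** — OLS slope (dB/octave) of harmonic amplitude
  against log₂ frequency over the first 8 harmonics; harmonic amplitudes are
  spectral maxima within ±f0/4 of each ideal harmonic.  Spectra use a Hann
  window zero-padded to the next power of two ≥ 4× the frame.  Candidates
  more than 80 dB below the strongest harmonic are numerically absent (a
  pure tone has one harmonic) and at least three real harmonics are required.
* **LH ratio** — 10·log₁₀ of spectral power below vs above 2 kHz, with both
  bands floored at 10⁻¹² of total power so the ratio stays finite.
* **CPP** — the power cepstrum is the squared inverse transform of the dB
  spectrum, smoothed with a 5-bin boxcar *before* the dB transform (the log
  of a near-zero cepstral bin otherwise drags the regression baseline down
  and inflates aperiodic frames), then expressed in dB; the peak over
  quefrencies [1/1000 s, 1/70 s] is referenced to an OLS line over that
  range.  On this scale clean glottal pulse trains read 13–26 dB, white
  noise < 8 dB; the measure is exactly scale-invariant.  The precise CPP
  normalization differs between published implementations; this one is a
  documented package choice.
* **Zero crossing rate** — sign changes of the mean-removed frame divided by
  frame length.

A frame is **voiced** iff f0 is present and every computable feature lies in
its configured range (SPL 45–130 dB, f0 70–1000 Hz, autocorrelation peak
0.60–1, subharmonic 0.25–1 via the octave-correction policy, tilt −25–0
dB/oct, LH 22–50 dB, CPP 10–35 dB, ZCR 0–1).  Absent features pass; the
decision is a pure conjunction, so widening any range can only increase the
voiced count.

## Vocal doses and segment structure

Phonation time is the voiced-frame count times the frame duration, also as a
percentage of monitored frames; an explicit pause mask excludes device-off
time from both numerator and denominator.  Cycle dose accumulates f0 ×
frame duration over voiced frames.  Distance dose accumulates 4·A(SPL)·f0 ×
frame duration, where the vibratory amplitude A = A₀·10^((SPL−P₀)/S) with
defaults A₀ = 1 mm at P₀ = 90 dB SPL and S = 40 dB per decade — constants
adopted from the vocal-dose literature's amplitude scaling, not fitted here;
tests exercise the structural properties (linearity, additivity), not the
constants.

Voicing-decision runs are run-length encoded; occurrence and accumulation
histograms use logarithmic duration bins from 50 ms to 300 s.  Phrase
smoothing absorbs unvoiced gaps *strictly shorter* than 0.5 s (the quoted
threshold is "<0.5 s") into surrounding voiced runs, approximating breath
groups; leading/trailing gaps are kept.  A 2-D histogram of (voiced run,
immediately following unvoiced run) durations per monitored hour summarizes
how much voice rest follows voicing bursts.

## Subglottal impedance-based inverse filtering (IBIF)

The subglottal airways are a cascade of T-equivalent segments of lumped
acoustic elements: series air inertance ρl/A and viscous (boundary-layer)
resistance per segment; shunt air compliance lA/ρc² in parallel with a
yielding-wall branch (resistance–mass–stiffness per unit wall area, divided
by the segment's wall surface).  Default geometry is an average symmetric
tract: a 10.5-cm trachea of 2.5 cm² followed by airway generations whose
cumulative cross-section e-folds every 3 cm, discretized into 15 segments
over 20 cm (doubling the segment count changes the in-band response by
< 4 dB; a convergence test guards this).  The peripheral end is terminated
resistively at the last segment's characteristic impedance ρc/A.  Warm humid
air: ρ = 1.14 kg/m³, c = 350 m/s, µ = 1.86·10⁻⁵ Pa·s.

At the sensor position the containing segment is *split exactly*, and a skin
branch hangs on the resulting ladder node: specific impedance
r + jω(m_skin + m_acc) + k/jω over an effective patch area.  The output is
the skin-normal acceleration jω·p_node/z_skin per unit glottal flow.  Skin
constants (per unit area): inertance 2 kg/m², resistance 2000 kg/m²s,
stiffness 4·10⁶ N/m³, accelerometer + epoxy + silicone-pad load 4 kg/m²,
effective coupled area 10 cm².  These are plausible for taut neck skin under
a mounted sensor assembly and were chosen jointly so that (a) the loaded
skin resonance (~130 Hz) sits inside the excited harmonic band and (b) the
unscaled load mass and the skin branch's loading of the tract anchor the
absolute skin-impedance scale — both are required for the five-parameter
subject calibration below to be well posed.  All constants live in two
dataclasses (`TractGeometry`/`SkinParams`) and are configurable.

Five dimensionless Q factors adapt the model per subject: q1–q3 scale skin
inertance, resistance, stiffness; q4 scales every segment length; q5 scales
the sensor position (bounds [0.1, 10], default 1).  Because the segment is
split at the exact scaled sensor position, the response is continuous in q5
rather than quantized to segment boundaries.

**Inversion.**  The flow estimate is the acceleration spectrum divided by
the transfer function with a Tikhonov floor at 10⁻³·max|H|; bins below
0.9 Hz are zeroed (the DC flow level is unobservable from an AC
acceleration signal) and the output is mean-free.  For noisy field-grade
recordings an optional band limit (default used in the noisy experiments:
2.5 kHz) truncates the region where the inverse filter mostly amplifies
sensor noise.

**Q calibration.**  The reference flow comes from oral airflow via
single-formant inverse filtering: an order-8 LPC envelope pole in
200–1200 Hz with radius ≥ 0.85 defines the anti-resonance (two conjugate
zeros, unit DC gain).  Poles below 1.6·f0 are rejected — LPC of a strongly
periodic source parks a spurious pole on the first harmonic.  A periodic but
resonance-free input passes through unchanged; an aperiodic input with no
stable pole is an error.

The five Q factors are fitted to sustained-vowel segments.  Each segment is
reduced to complex harmonic amplitudes at multiples of f0 (estimated by
direct sinusoidal projection after refining f0 to ~10⁻⁵ relative — the
frequency-domain equivalent of pitch-synchronous averaging, whose noise
variance shrinks with segment length).  The candidate model maps the
reference-flow harmonics to predicted acceleration harmonics, compared with
the measured ones under the best complex gain and ±10 ms time shift;
absolute gain is uninformative because the oral-airflow and acceleration
pathways are calibrated independently, and matching in the acceleration
domain keeps the sensor noise white across harmonics.  The mean normalized
residual over segments is minimized by bounded Nelder–Mead from q = 1 plus
seeded Latin-hypercube multistarts.  Pooling the protocol's three
calibration vowels (soft/comfortable/loud, different f0) is strongly
recommended: their interleaved harmonic grids sample the transfer function
three times as densely and pin down the joint skin-impedance scale that a
single vowel determines only weakly.  Under these conditions, 20%
perturbations of all five factors are recovered within 10% each at 20 dB
SNR; with a single short vowel the estimate can slide tens of percent along
the skin-scale direction.

**Glottal measures.**  Cycle boundaries are waveform minima between pulse
peaks (peaks are robust to closed-phase ripple in inverse-filtered signals);
ties across a flat closed phase break to the plateau middle so both flanks
stay interior to the cycle.  Opening/closing instants are crossings of
baseline + α·AC (α = 0.05) on each flank with per-flank baselines,
extrapolated back to baseline along the local slope — exact for
piecewise-linear pulses.  MFDR uses a local linear-slope differentiator
(Savitzky–Golay, window 5, order 1): exact on linear segments, ~5× less
noise variance than a central difference.  OQ = tO/(tO+tC),
SQ = 100·t_op/t_cp, NAQ = (AC/MFDR)/(tO+tC); H1–H2 comes from the spectrum
of a ≥ 4-cycle window.  Per-cycle values are averaged over 50-ms frames with
50% overlap (a cycle joins every frame containing its midpoint; empty frames
are omitted).  The SPL/log-MFDR regression converts MFDR to dB (20·log₁₀)
and reports the OLS slope of SPL on MFDR-dB with the correlation.

## Windowed classification

Frame streams are cut into non-overlapping windows of 6000 frames (the
5-minute window is *defined* as 6000 50-ms frames; at 11 025 Hz a 50-ms
frame is floored to 551 samples, so 6000 frames span 299.86 s of signal).
Windows with fewer than 30 voiced frames (0.5% phonation) are excluded.
Raw statistics over voiced-frame SPL and f0 — mean, SD (ddof 1), skewness,
kurtosis (raw moment convention: 3 for a normal), 5th/95th percentile by
linear interpolation — plus percent phonation form the feature set.
Normalized counterparts express each statistic in SD units of its baseline:
the windows whose start time falls in the first half of the subject-day's
monitored span, pooled (a per-hour-averaged mode is provided; pooled is the
default since the two readings of "an average hour" differ only in weighting).
A zero baseline SD yields a flagged 0.

Classification is an L1-penalized logistic regression (LASSO) per
leave-one-pair-out fold: each fold holds out one patient–control pair,
standardizes features on its training windows, selects the penalty by inner
5-fold cross-validation over pairs with the one-standard-error rule (a
fixed-penalty mode gives a fully reproducible path), and labels each
held-out window at probability > 0.5.  A subject is called a patient when
*strictly more than* a proportion τ of their windows are patient-labeled
(default τ = 0.5; a seeded 0.01-step sweep reports the accuracy-maximizing
τ, ties to the smallest).  Reported metrics: subject accuracy, F-score,
sensitivity, specificity, and the per-fold AUC over held-out window
probabilities (mean, SD).  The coefficient table counts folds with positive
(patient-associated) and negative (control-associated) signs and summarizes
exp(β) odds ratios.

## Synthetic data: what it emulates and what it does not

The generators make every stage testable without recordings, and their
defaults are the conditions the tests run under:

* `synth_glottal_flow` — triangular (default) or raised-cosine pulse trains
  with per-cycle closed forms: OQ = open fraction, SQ = 100·speed ratio,
  MFDR = AC/t_cp (triangle) or πAC/2t_cp (cosine), NAQ = t_cp/T (triangle).
  Cycle start times accumulate continuous periods, so cycles are not
  sample-aligned and quantization is exercised.  The triangular family is
  the default because its closed forms make the oracle tests exact; it is
  not a physiological flow model (no source–filter ripple, no aspiration
  noise, no cycle-to-cycle perturbation unless noise is added).
* `synth_acc_signal` — forward simulation plus white noise scaled to exactly
  the stated SNR.  Real sensor noise is not white and includes motion
  artifacts; passing the 10% round-trip bound here shows self-consistency
  of the model and inversion, not field accuracy.
* `synth_day_frames` — frame records drawn per hour from stated
  voiced-fraction and SPL/f0 distributions (normal or lognormal samplers).
  No temporal autocorrelation of voicing; dose and window statistics are
  exercised, conversational structure is not.
* `synth_cohort` — paired subjects whose *normalized* window statistics are
  drawn N(shift, 1) for patients and N(0, 1) for controls (plus a 0.3-SD
  between-subject offset), with raw statistics around plausible ambulatory
  values.  The default effect right-shifts normalized SPL skew and
  normalized f0 95th percentile by 1.5 SD — the directionality reported for
  phonotraumatic vocal hyperfunction — in 20 pairs × 50 windows.  Passing
  the ≥ 90% accuracy and feature-selection checks shows the LOOCV/LASSO
  machinery recovers a known injected effect; it says nothing about
  real-cohort effect sizes.

All generators are deterministic under a fixed seed.

## Numerical choices and degenerate inputs

Frame length floor(fs·duration) with trailing samples dropped; silent floor
10⁻⁶ full scale; lh floor 10⁻¹²; Tikhonov floor 10⁻³·max|H|; cycle
α = 0.05; h1h2 harmonic search ±25% around k·f0; LASSO penalty grid 10
points, λ ∈ [0.01, 10], strongest first for the 1-SE rule.  Degenerate
inputs: constant frames are silent/zero-ZCR; single-class labels, incomplete
pairs, constant calibration levels, and zero-variance regressions raise
errors naming the violation; zero-variance window statistics and baselines
are flagged zeros rather than errors because they occur in sparse but valid
windows.

## Problem sizes used in the checks

The packaged checks run at desk scale by design: 1–3 s signals for signal
oracles, a 2-s pulse train (~400 cycles) for the inversion experiment,
three 3-s vowels for Q calibration, and 20 pairs × 50 windows for the
cohort experiments.  A weeklong recording is ~10⁴× more data; nothing in
the implementation depends on duration except memory for the FFT buffers.

## Known limitations

The transmission-line constants are plausible defaults, not fitted to any
subject; absolute flow units out of the inversion are arbitrary (only the
acceleration pathway's scale is known).  Q calibration assumes a stable
sustained vowel and a time-invariant subglottal system; whether Q should be
re-estimated per loudness condition is left open (per-segment re-fitting is
available but not endorsed).  The voicing decision is frame-local with no
hidden-state smoothing.  The classifier ignores time of day and window
order by construction.
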