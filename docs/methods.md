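# Methods

## Scope and intent

`oxibench` emulates, in software, a bench protocol in which a patient
simulator drives an SpO₂ functional tester that presents optical stimuli to
pulse-oximeter finger sensors. Everything physical — simulator, tester,
sensors, monitors — is replaced by a signal model, a sensor-corruption
model, and virtual estimators. The package therefore measures properties of
*its own* virtual devices under controlled signal conditions; it makes no
claims about any marketed oximeter.

## Signal model

The stimulus is the functional-tester abstraction, not a tissue-optics
(Beer–Lambert multi-chromophore) model. For a setting (%T, %MOD, SpO₂, HR):

* `I_ir(t) = %T · (1 + (%MOD/100)·w(t))`
* `I_red(t) = %T · (1 + (R·%MOD/100)·w(t))`

with `w` a zero-mean, unit peak-to-peak pulse waveform repeated at HR/60 Hz
and `R` the ratio-of-ratios implied by SpO₂ through the calibration curve.
Conventions, each a deliberate design choice:

* **%MOD is the infrared perfusion index.** The commanded %MOD is carried
  by the IR channel; the red channel carries `R·%MOD`, making the noiseless
  ratio-of-ratios exactly `R`. This matches how functional testers encode
  saturation.
* **%MOD uses the peak-to-peak amplitude convention** (peak-to-peak of the
  cardiac component divided by DC, ×100). Other amplitude conventions
  (e.g. RMS) would rescale %MOD by a waveform-dependent constant.
* **Both channels share one DC equal to %T.** Real red/IR DC levels differ;
  a `dc_ratio` parameter (default 1) exposes that extension, but the
  benchmark treats %T as the single translucency scalar.
* **Calibration curve**: linear `SpO₂ = 110 − 25·R` by default, a standard
  textbook approximation; the curve object is pluggable (a quadratic term
  is built in) and strictly decreasing on its validity range, with the
  inverse exact to 1e-9 over SpO₂ ∈ [65, 95].
* **Pulse template** (`child_nsr`): a stylized pediatric normal-sinus-rhythm
  pulse built from two Gaussian lobes — systolic peak at 18% of the period
  and a dicrotic bump at 60%, amplitude ratio 4:1, both with width
  σ = 0.12 periods. The widths were chosen at design time so that the first
  two Fourier harmonics carry ≈99% of the peak-to-peak amplitude, which the
  spectral estimator's two-harmonic reconstruction exploits; the waveform's
  proprietary hardware counterpart is unpublished, and the template shape
  affects beat detection but none of the definitional DC/AC contracts.
* Sampling: 125 Hz, 45 s per combination (the session length of the
  emulated protocol). Respiration, motion and ambient-light artifacts are
  deliberately absent (best-case scenario).

## Sensor model

Each virtual finger sensor applies, per channel: a multiplicative AC-path
gain error (DC preserved), additive white Gaussian noise, and optional
quantization (off by default, since hardware auto-ranging makes its
placement ambiguous). Defaults: gain spread sd 0.005 around 1, noise sd
2×10⁻⁴ %T-units.

The noise is *absolute* — a constant detector/electronics floor independent
of the light level. This single assumption produces the benchmark's central
stressor: the AC-relative SNR is proportional to %T·%MOD, so halving %T
halves the SNR, and settings with %T ≤ 1 become genuinely hard. Gains model
persistent sensor-to-sensor spread (a fixed bank per session, as with
physically labeled sensors); noise is redrawn per (setting, sensor) with a
seed derived from the master seed and the *setting's identity*, so both
device profiles always see the identical corrupted stimulus and sweep
results are independent of enumeration order.

## Virtual estimators

Both arms share the reading loop: 8 s sliding windows stepped every 1 s
after a 10 s settling period (≈36 readings from a 45 s session), heart rate
from the Hann-windowed, 4×-zero-padded IR periodogram peak in 0.5–4 Hz
(parabolic refinement; a window whose peak is below 8× the median band
power yields an invalid reading), per-channel DC as the window mean, the
ratio-of-ratios from the AC/DC pairs, calibration lookup with clipping to
[0, 100], and exponential display smoothing (factor 0.3) across valid
readings. Invalid readings are retained with `valid=false` and excluded
from error averaging; there is no other exclusion rule.

* **`profile_robust` (spectral)**: complex amplitudes at the cardiac
  fundamental and its second harmonic are measured by Hann-weighted
  projection and the two-harmonic waveform's peak-to-peak amplitude is
  returned. A pure sinusoid of amplitude a yields 2a; broadband noise
  biases the estimate only through the power inside the two narrow bands,
  which is negligible at the default noise floor.
* **`profile_naive` (beatwise)**: beats are detected on the 5 Hz
  low-pass-filtered IR trace (minimum peak separation of half the estimated
  cardiac period, earliest-sample tie-break); the AC estimate is the median
  over complete beats of the raw window's per-beat max − min. Additive
  noise inflates each per-beat range by roughly the expected range of the
  noise over a beat, so the arm degrades as the absolute AC amplitude
  shrinks, and — because the inflation is the same in absolute terms on
  both channels — pulls the measured ratio-of-ratios toward 1, making
  errors largest at low SpO₂ (R = 1.8 at SpO₂ 65 versus 0.6 at 95).

These are *designed* robustness/susceptibility mechanisms. The averaging
times, window lengths and smoothing of real devices are unpublished; the
defaults are plausible and configurable, never asserted against vendor
behavior.

## Protocol and metrics

The grid (4 %T × 5 %MOD × 7 SpO₂ × 4 HR = 560 settings) is enumerated with
%T varying most slowly, then %MOD, then SpO₂, with HR innermost, each list
ascending (the enumeration direction is a convention; results are
order-independent). A full sweep over 2 profiles × 7 sensors yields 7,840
records.

* **Per-setting score**: weighted average over sensors of the per-sensor
  mean signed error, weights = valid-reading counts, reported as an
  absolute value. The phrase "mean error expressed as absolute value"
  admits a second reading — the weighted mean of per-sensor absolute
  errors — which is implemented behind `absolute_first=True` and reported
  alongside the default in the metrics table.
* **Flagging**: strictly greater than 3% (an error of exactly 3.0 is not
  flagged).
* **Per-region, per-sensor aggregate**: valid-count-weighted mean over the
  region's 28 (SpO₂ × HR) settings of the absolute per-setting mean error,
  consistent with the per-setting weighting.
* **Welch comparison**: unequal-variance t-test with Satterthwaite degrees
  of freedom and 95% CI of the difference in means, computed through
  statsmodels and cross-checked in the tests against an independently coded
  textbook implementation to 1e-10. Two constant, equal groups return
  p = 1 / t = 0 / zero-width CI rather than erroring (the noiseless
  integration tests hit this case). No multiple-testing correction is
  applied across the four default regions.

## Synthetic NICU reference

The clinical epoch-level dataset the benchmark contextualizes against is
unavailable; the generator is a parametric stand-in fitted to its published
summaries only (range, median, and one quantile bound per axis):

* %T: log-normal, median 3.69, log-sd 0.85, truncated by rejection to
  [0.43, 37.70]. The log-sd is the one free parameter; 0.85 places the
  truncation bounds near ±2.5–2.7 log-sd, so the printed extremes are rare
  but reachable, as befits observed min/max values of a ~1,500-epoch
  sample.
* %MOD: mixture of log-normal (median 1.30, log-sd 0.30, weight 0.97) and a
  wide tail (same median, log-sd 1.2, weight 0.03), truncated to
  [0.23, 8.04]. A single log-normal cannot simultaneously keep ≥90% of its
  mass at or below 2.0 and plausibly populate a maximum of 8.04; the small
  wide-tailed component resolves that (the shipped law puts ≈92% below
  2.0).
* 34 subjects, skin-tone counts (1, 8, 15, 10) for extremely dark / dark
  olive / olive / very light; epochs are assigned to subjects round-robin.
  Skin tone is carried as a label only — no quantitative tone→%T mapping is
  invented, because only the direction of such an effect is known.
* The two axes are sampled independently; the real joint (%T, %MOD)
  dependence is unpublished and not modeled. Only the marginals are
  calibrated, so coverage statistics over joint regions are indicative, not
  inferential.

The 2-D density used in the overlay is a probability-mass histogram on
log-spaced bins (sums to 1 over the grid).

## What the synthetic conditions do and do not show

Passing tests demonstrate that the *pipeline* behaves as designed under the
stated signal model: exact noiseless recovery, noise-driven separation of
the two estimator arms at %T ≤ 1 with agreement at %T = 4.49, error bias
toward low SpO₂, and a NICU-like reference distribution matching its
published summaries. They do not establish anything about real devices or
real neonatal tissue: the stimulus lacks motion, respiration, ambient
light, red/IR DC asymmetry and waveform variability, the sensor model's
gain/noise levels are plausible but uncalibrated, and the reference
distribution reproduces marginals, not the clinical joint distribution.

## Numerical choices and degenerate inputs

* HR search band 0.5–4 Hz; windows must span ≥4 s (HR) and ≥4 cardiac
  periods (spectral AC). Constant windows raise a no-cardiac-signal
  condition, which the reading loop converts to `valid=false`.
* Beatwise extraction needs ≥2 complete beats (3 detected peaks).
* The calibration inverse validates its input against the curve image;
  estimator-side conversion clips to [0, 100] with a logged warning
  instead (a display must always show something).
* Sweep failures of any single combination are captured as records with
  `n_valid = 0`; a sweep never aborts.
* Seeds: one master seed; sensor banks and per-(setting, sensor) noise
  streams derive children via `numpy` seed sequences; all derived seeds are
  below 2³¹.

## Problem sizes in the shipped tests

The full noiseless grid check runs all 560 settings × both profiles at the
default 45 s / 125 Hz session. The noisy separation check sweeps three %T
columns at %MOD = 1.1 (84 settings × 7 sensors × 2 profiles). Monte-Carlo
properties of the estimators use 30–100 seeded replicates at 20 s session
length, and the protocol-count check uses 19 s sessions (record counts are
structural, independent of session length). The NICU calibration checks use
10⁴–10⁵ epochs.
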