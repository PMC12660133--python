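# oxibench

In-silico bench testing of pulse oximetry under neonatal low-translucency /
low-perfusion conditions.

Pulse oximeters are clinically verified on healthy adults, yet some of their
hardest operating conditions occur in the NICU: darkly pigmented or thick
tissue sites transmit little LED light (low percent transmission, **%T**),
and immature perfusion makes the pulsatile signal small relative to its
baseline (low percent modulation, **%MOD**). `oxibench` is a software
analogue of a functional-tester bench: it synthesizes two-wavelength
(red/infrared) transmission photoplethysmography stimuli over a stress grid
of (%T, %MOD, SpO₂, HR), presents them to configurable *virtual* oximeters
through replicated virtual finger sensors, and scores each device with a
weighted mean SpO₂ error, a 3% performance-concern flag, and Welch
(unequal-variance) comparisons across regions of the (%T, %MOD) signal
space. A synthetic NICU reference distribution of epoch-level (%T, %MOD)
medians situates the grid relative to clinically observed conditions.

It is intended for researchers and device engineers prototyping
pre-clinical, simulator-based verification protocols — not for evaluating
any real marketed device: the shipped estimator arms are stylized
mechanisms, not reverse-engineered vendor algorithms.

## The signal model and the metric

Each grid setting commands a stimulus

```
I_ir(t)  = %T · (1 + (%MOD/100) · w(t))
I_red(t) = %T · (1 + (R·%MOD/100) · w(t))
```

where `w` is a zero-mean, unit peak-to-peak cardiac pulse waveform repeated
at the commanded heart rate, and `R` is the ratio-of-ratios
`(AC_red/DC_red)/(AC_ir/DC_ir)` implied by the commanded SpO₂ through a
calibration curve (default: the textbook linear approximation
`SpO₂ = 110 − 25·R`). Virtual sensors add per-channel AC gain errors and a
constant-level Gaussian detector noise floor — the mechanism by which low
%T·%MOD conditions destroy signal-to-noise ratio.

A device's score at one setting is the valid-reading-count-weighted average
over the sensor bank of the difference between reported and commanded SpO₂,
expressed as an absolute value; values above 3% flag a performance concern.
For regional statistics, each sensor's mean absolute error over all
(SpO₂ × HR) settings at a fixed (%T, %MOD) point is computed per device,
and the two seven-sensor samples are compared with Welch's t-test
(Satterthwaite degrees of freedom, two-sided p, 95% CI).

## Worked example

```python
import numpy as np
from oxibench import (SimSetting, synthesize_optical_signal, apply_sensor_model,
                      make_sensor_bank, run_estimator, PROFILE_ROBUST, PROFILE_NAIVE)

setting = SimSetting(t_pct=0.39, mod_pct=1.1, spo2_pct=65, hr_bpm=120)
signal = synthesize_optical_signal(setting)              # 45 s at 125 Hz
sensor = make_sensor_bank(n_sensors=1, master_seed=0)[0]
noisy = apply_sensor_model(signal, sensor)
for profile in (PROFILE_ROBUST, PROFILE_NAIVE):
    readings = run_estimator(noisy, profile)
    err = np.mean([abs(r.spo2_pct - 65) for r in readings if r.valid])
    print(f"{profile.name}: mean |SpO2 error| = {err:.2f}%")
```

prints

```
profile_robust: mean |SpO2 error| = 0.26%
profile_naive: mean |SpO2 error| = 2.16%
```

At %T = 0.39 (a translucency below anything observed in the reference NICU
cohort) and %MOD = 1.1, the spectral-estimator profile still reads within a
quarter percentage point of the commanded 65% saturation, while the
beat-by-beat profile — whose per-beat amplitude estimate is inflated by the
detector noise floor — errs by about 2%. Aggregating a sweep over seven
sensors and Welch-comparing the profiles per region:

```
(%T=0.39, %MOD=1.1): robust 0.13% vs naive 1.23%, p = 0.0000, 95% CI [1.00, 1.20]
(%T=4.49, %MOD=1.1): robust 0.11% vs naive 0.12%, p = 0.8973, 95% CI [-0.11, 0.13]
```

— the two virtual devices are indistinguishable at comfortable
translucency and separate sharply (p < 0.05, CI excluding zero) where the
light budget is scarce, with errors largest at low SpO₂.

## Command line

```bash
oxibench sweep --out results/              # full 560-setting benchmark (default config)
oxibench compare --results results/results.csv --out results/regions.csv
oxibench nicu-sim --n 10000 --seed 1 --out results/nicu.csv
oxibench plot --metrics results/metrics.csv --nicu results/nicu.csv --out results/map.png
```

`sweep` writes a long-format per-(setting × sensor × profile) results CSV,
a per-(setting × profile) metrics CSV, the validated config used, and a run
log. `plot` renders the nested-inset error map: log-log (%T, %MOD) master
axes, one inset per grid point (HR × SpO₂, red where the error exceeds 3%),
with the synthetic NICU density overlaid.

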