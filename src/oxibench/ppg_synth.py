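"""Two-wavelength transmission PPG signal synthesis.

This module generates the optical stimulus a functional tester would present
to a pulse oximeter sensor: a red and an infrared transmitted-light trace,
expressed in percent-transmission (%T) units, whose measurable properties —
DC level, percent modulation (%MOD), cardiac fundamental frequency, and
ratio-of-ratios — equal commanded values exactly by construction.

The signal model is the functional-tester abstraction, not tissue optics:

    I_ir(t)  = %T · dc_ratio⁰ · (1 + (%MOD/100) · w(t))
    I_red(t) = %T · dc_ratio  · (1 + (R·%MOD/100) · w(t))

where ``w`` is a zero-mean, unit peak-to-peak cardiac pulse waveform repeated
at the commanded heart rate and ``R`` is the ratio-of-ratios implied by the
commanded SpO₂ through the calibration curve.  The commanded %MOD is carried
by the infrared channel (the perfusion-index convention of functional
testers); the red channel carries R·%MOD so that the noiseless
ratio-of-ratios is exactly R.  Both channels share the same DC by default
(``dc_ratio=1``); real sensors have unequal red/IR DC, which can be emulated
through ``dc_ratio``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SimSetting",
    "PulseTemplate",
    "OpticalSignal",
    "CalibrationCurve",
    "SensorModel",
    "DEFAULT_CURVE",
    "make_pulse_template",
    "spo2_to_ratio",
    "synthesize_optical_signal",
    "apply_sensor_model",
]

DEFAULT_SAMPLE_RATE = 125.0  # Hz
DEFAULT_DURATION = 45.0  # s, one test-session recording per grid combination


@dataclass(frozen=True)
class SimSetting:
    """One grid point of the bench protocol.

    Parameters
    ----------
    t_pct : float
        Percent transmission (%T), the fraction (×100) of emitted LED light
        reaching the photodetector.  Proxy for tissue translucency.
    mod_pct : float
        Percent modulation (%MOD), the pulsatile-to-constant (AC/DC) ratio
        (×100) of the transmitted-light signal; a perfusion-index-like value.
    spo2_pct : float
        Commanded peripheral oxygen saturation, percent.
    hr_bpm : float
        Commanded heart rate, beats per minute.
    """

    t_pct: float
    mod_pct: float
    spo2_pct: float
    hr_bpm: float

    def __post_init__(self) -> None:
        if not self.t_pct > 0:
            raise ValidationError(f"t_pct must be > 0, got {self.t_pct}")
        if not self.mod_pct > 0:
            raise ValidationError(f"mod_pct must be > 0, got {self.mod_pct}")
        if not self.mod_pct < 100:
            raise ValidationError(f"mod_pct must be < 100, got {self.mod_pct}")
        if not 0 < self.spo2_pct <= 100:
            raise ValidationError(
                f"spo2_pct must be in (0, 100], got {self.spo2_pct}"
            )
        if not self.hr_bpm > 0:
            raise ValidationError(f"hr_bpm must be > 0, got {self.hr_bpm}")


@dataclass(frozen=True)
class PulseTemplate:
    """One cardiac period of a dimensionless pulse waveform.

    ``samples`` hold one full period; the waveform is normalized to zero mean
    and unit peak-to-peak amplitude and continues periodically (the builder
    guarantees continuity at the wrap point by construction).
    """

    samples: np.ndarray
    sample_rate: float
    label: str

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 1 or s.size < 8:
            raise ValidationError("samples must be a 1-D array of >= 8 points")

    def evaluate(self, phase: np.ndarray) -> np.ndarray:
        """Evaluate the waveform at arbitrary cardiac phase (period = 1).

        Linear interpolation on the stored period with periodic wrapping.
        """
        ph = np.asarray(phase, dtype=float) % 1.0
        n = self.samples.size
        grid = np.arange(n + 1) / n
        wrapped = np.concatenate([self.samples, self.samples[:1]])
        return np.interp(ph, grid, wrapped)

    def harmonic_amplitudes(self, k_max: int = 2) -> np.ndarray:
        """Amplitudes of the first ``k_max`` Fourier harmonics of the period."""
        c = np.fft.rfft(self.samples) / self.samples.size
        return 2.0 * np.abs(c[1 : k_max + 1])


def _child_nsr(sample_rate: float) -> np.ndarray:
    # Two-lobe pulse: systolic peak at 18% of the period plus a dicrotic bump
    # at 60%, amplitude ratio 4:1.  Widths chosen broad enough that the first
    # two harmonics carry ~99% of the peak-to-peak amplitude, which the
    # spectral AC extractor exploits.
    n = max(64, int(round(sample_rate)))
    p = np.arange(n) / n
    w = np.zeros(n)
    for shift in (-1.0, 0.0, 1.0):
        w += np.exp(-0.5 * ((p - 0.18 + shift) / 0.12) ** 2)
        w += 0.25 * np.exp(-0.5 * ((p - 0.60 + shift) / 0.12) ** 2)
    return w


_TEMPLATE_BUILDERS: dict[str, Callable[[float], np.ndarray]] = {
    "child_nsr": _child_nsr,
}


def make_pulse_template(label: str = "child_nsr", sample_rate: float = DEFAULT_SAMPLE_RATE) -> PulseTemplate:
    """Build a named cardiac pulse template, normalized to zero mean and unit
    peak-to-peak amplitude.

    Parameters
    ----------
    label : str
        Waveform name.  ``"child_nsr"`` is the shipped default, a stylized
        pediatric normal-sinus-rhythm pulse (systolic lobe plus dicrotic bump).
    sample_rate : float
        Sampling rate (Hz) used to discretize one period; must be >= 50 Hz.
    """
    if sample_rate < 50:
        raise ValidationError(f"sample_rate must be >= 50 Hz, got {sample_rate}")
    try:
        builder = _TEMPLATE_BUILDERS[label]
    except KeyError:
        raise ValidationError(
            f"unknown template {label!r}; available: {sorted(_TEMPLATE_BUILDERS)}"
        ) from None
    w = builder(float(sample_rate))
    w = w - w.mean()
    w = w / np.ptp(w)
    w = w - w.mean()  # re-center after scaling (no-op numerically, but exact)
    return PulseTemplate(samples=w, sample_rate=float(sample_rate), label=label)


@dataclass(frozen=True)
class CalibrationCurve:
    """Invertible monotone-decreasing mapping between the ratio-of-ratios R
    and SpO₂ (%).

    SpO₂(R) = intercept + slope·R + quad·R², valid for R in
    [r_min, r_max].  The default is the textbook linear approximation
    SpO₂ = 110 − 25·R; an empirical quadratic can be supplied through
    ``quad``.  The curve must be strictly decreasing on its validity range.
    """

    intercept: float = 110.0
    slope: float = -25.0
    quad: float = 0.0
    r_min: float = 0.1
    r_max: float = 4.0

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValidationError("r_min must be < r_max")
        # strict monotone decrease: derivative slope + 2 quad R < 0 on range
        d_lo = self.slope + 2 * self.quad * self.r_min
        d_hi = self.slope + 2 * self.quad * self.r_max
        if not (d_lo < 0 and d_hi < 0):
            raise ValidationError(
                "calibration curve must be strictly decreasing on [r_min, r_max]"
            )

    def spo2(self, r: float | np.ndarray) -> float | np.ndarray:
        """SpO₂ (%) at ratio-of-ratios ``r`` (not range-checked; callers clip)."""
        return self.intercept + self.slope * r + self.quad * r**2

    @property
    def spo2_min(self) -> float:
        return float(self.spo2(self.r_max))

    @property
    def spo2_max(self) -> float:
        return float(self.spo2(self.r_min))

    def ratio(self, spo2_pct: float) -> float:
        """Invert the curve: the R with SpO₂(R) = ``spo2_pct``.

        Raises :class:`ValidationError` if ``spo2_pct`` lies outside the
        curve's image on [r_min, r_max].
        """
        lo, hi = self.spo2_min, self.spo2_max
        if not (lo <= spo2_pct <= hi):
            raise ValidationError(
                f"spo2_pct {spo2_pct} outside calibration image [{lo:g}, {hi:g}]"
            )
        if self.quad == 0.0:
            return (spo2_pct - self.intercept) / self.slope
        # quadratic: pick the root inside the validity range
        a, b, c = self.quad, self.slope, self.intercept - spo2_pct
        disc = b * b - 4 * a * c
        roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1.0, -1.0)]
        for r in roots:
            if self.r_min - 1e-12 <= r <= self.r_max + 1e-12:
                return float(np.clip(r, self.r_min, self.r_max))
        raise ValidationError(f"no valid root inverting curve at {spo2_pct}")


DEFAULT_CURVE = CalibrationCurve()


def spo2_to_ratio(spo2_pct: float, curve: CalibrationCurve = DEFAULT_CURVE) -> float:
    """Ratio-of-ratios R commanded by a target SpO₂ under ``curve``."""
    return curve.ratio(spo2_pct)


@dataclass(frozen=True)
class OpticalSignal:
    """Sampled two-channel transmitted-light trace in %T units."""

    red: np.ndarray
    ir: np.ndarray
    sample_rate: float
    duration: float
    setting: SimSetting

    def __post_init__(self) -> None:
        red = np.asarray(self.red, dtype=float)
        ir = np.asarray(self.ir, dtype=float)
        object.__setattr__(self, "red", red)
        object.__setattr__(self, "ir", ir)
        if red.shape != ir.shape or red.ndim != 1:
            raise ValidationError("red and ir must be 1-D arrays of equal length")

    @property
    def n_samples(self) -> int:
        return int(self.red.size)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def to_frame(self) -> pd.DataFrame:
        """Plain-text-exportable view: columns time_s, red, ir."""
        return pd.DataFrame({"time_s": self.time, "red": self.red, "ir": self.ir})


def synthesize_optical_signal(
    setting: SimSetting,
    template: PulseTemplate | None = None,
    curve: CalibrationCurve = DEFAULT_CURVE,
    duration: float = DEFAULT_DURATION,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    dc_ratio: float = 1.0,
) -> OpticalSignal:
    """Generate the noiseless two-wavelength stimulus for one grid setting.

    The returned signal satisfies, by construction: per-channel DC equal to
    ``setting.t_pct`` (times ``dc_ratio`` on red), IR peak-to-peak/DC equal to
    ``setting.mod_pct``/100, cardiac fundamental at ``setting.hr_bpm``/60 Hz,
    and ratio-of-ratios equal to the calibration curve's R at the commanded
    SpO₂.
    """
    if template is None:
        template = make_pulse_template(sample_rate=sample_rate)
    if duration <= 0:
        raise ValidationError(f"duration must be > 0, got {duration}")
    if sample_rate < 50:
        raise ValidationError(f"sample_rate must be >= 50 Hz, got {sample_rate}")
    if dc_ratio <= 0:
        raise ValidationError(f"dc_ratio must be > 0, got {dc_ratio}")
    r = curve.ratio(setting.spo2_pct)
    if r * setting.mod_pct >= 100:
        raise ValidationError(
            f"red modulation depth R*mod_pct = {r * setting.mod_pct:g} must be < 100"
        )
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    w = template.evaluate(t * setting.hr_bpm / 60.0)
    ir = setting.t_pct * (1.0 + (setting.mod_pct / 100.0) * w)
    red = setting.t_pct * dc_ratio * (1.0 + (r * setting.mod_pct / 100.0) * w)
    return OpticalSignal(
        red=red, ir=ir, sample_rate=float(sample_rate), duration=float(duration), setting=setting
    )


@dataclass(frozen=True)
class SensorModel:
    """A virtual finger sensor: AC-path gain errors, detector noise, optional
    quantization.

    ``gain_red``/``gain_ir`` scale only the pulsatile (AC) component of each
    channel, leaving DC untouched — the mechanism behind sensor-to-sensor
    spread of the measured ratio-of-ratios.  ``noise_sigma`` is the standard
    deviation of additive white Gaussian detector noise in absolute %T units
    (a constant noise floor, which is what makes low-%T signals noisy in
    relative terms).  Corruption is bit-for-bit reproducible under
    ``rng_seed``.
    """

    sensor_id: int
    gain_red: float = 1.0
    gain_ir: float = 1.0
    noise_sigma: float = 0.0
    quantization_step: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.gain_red > 0 and self.gain_ir > 0):
            raise ValidationError("sensor gains must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.quantization_step < 0:
            raise ValidationError("quantization_step must be >= 0")


def apply_sensor_model(signal: OpticalSignal, sensor: SensorModel) -> OpticalSignal:
    """Corrupt a clean optical signal the way one physical sensor would.

    Per channel, in order: scale the AC component about the channel DC by the
    channel gain, add i.i.d. zero-mean Gaussian noise of sd ``noise_sigma``,
    then (if ``quantization_step > 0``) round to the quantization grid.  The
    red channel's noise is drawn before the infrared's, so the corruption is
    deterministic under ``rng_seed``.
    """
    rng = np.random.default_rng(sensor.rng_seed)
    out = []
    for channel, gain in ((signal.red, sensor.gain_red), (signal.ir, sensor.gain_ir)):
        dc = channel.mean()
        x = dc + gain * (channel - dc)
        if sensor.noise_sigma > 0:
            x = x + rng.normal(0.0, sensor.noise_sigma, size=x.size)
        if sensor.quantization_step > 0:
            x = np.round(x / sensor.quantization_step) * sensor.quantization_step
        out.append(x)
    return replace(signal, red=out[0], ir=out[1])
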