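"""Bench-test protocol: grid enumeration, sensor banks, and the full sweep.

The protocol mirrors an automated functional-tester session: a nested-loop
parameter grid (percent transmission varies most slowly, then percent
modulation, then SpO₂, with heart rate in the innermost loop), a bank of
virtual finger sensors measured sequentially at every grid point, and one
45 s recording per (setting × sensor) from which every device profile reads.

Both device profiles see the *same* corrupted stimulus at a given
(setting, sensor): per-combination noise seeds are derived deterministically
from ``(master_seed, setting index, sensor_id)``, the virtual analogue of two
physical monitors measuring the same artificial finger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ppg_synth import (
    DEFAULT_CURVE,
    DEFAULT_DURATION,
    DEFAULT_SAMPLE_RATE,
    CalibrationCurve,
    OpticalSignal,
    PulseTemplate,
    SensorModel,
    SimSetting,
    apply_sensor_model,
    make_pulse_template,
    synthesize_optical_signal,
)
from .virtual_oximeter import DeviceProfile, run_estimator

__all__ = [
    "GridSpec",
    "SweepRecord",
    "SynthConfig",
    "default_grid",
    "enumerate_grid",
    "make_sensor_bank",
    "run_sweep",
    "records_to_frame",
    "SWEEP_COLUMNS",
]

logger = logging.getLogger(__name__)

SWEEP_COLUMNS = [
    "t_pct",
    "mod_pct",
    "spo2_pct",
    "hr_bpm",
    "profile",
    "sensor_id",
    "n_valid",
    "n_total",
    "mean_signed_error",
    "mean_abs_error",
]


def _validated_values(name: str, values) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) == 0:
        raise ValidationError(f"{name} must be non-empty")
    if any(v <= 0 for v in vals):
        raise ValidationError(f"{name} must be strictly positive")
    if len(set(vals)) != len(vals):
        raise ValidationError(f"{name} must be duplicate-free")
    return vals


@dataclass(frozen=True)
class GridSpec:
    """The four parameter lists spanned by the bench protocol."""

    t_values: tuple[float, ...]
    mod_values: tuple[float, ...]
    spo2_values: tuple[float, ...]
    hr_values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "t_values", _validated_values("t_values", self.t_values))
        object.__setattr__(self, "mod_values", _validated_values("mod_values", self.mod_values))
        object.__setattr__(self, "spo2_values", _validated_values("spo2_values", self.spo2_values))
        object.__setattr__(self, "hr_values", _validated_values("hr_values", self.hr_values))

    def __len__(self) -> int:
        return (
            len(self.t_values)
            * len(self.mod_values)
            * len(self.spo2_values)
            * len(self.hr_values)
        )


def default_grid() -> GridSpec:
    """The neonatal-critical stress grid: 4 × 5 × 7 × 4 = 560 settings.

    %T values roughly log-span the lower half of the NICU-observed
    translucency range (exceeding its low end); %MOD values log-span the
    NICU perfusion range; SpO₂ spans roughly the 5th–97th percentile of
    at-birth saturations; HR spans the low end of NICU heart rates.
    """
    return GridSpec(
        t_values=(0.39, 0.87, 1.98, 4.49),
        mod_values=(0.2, 0.4, 0.6, 1.1, 2.0),
        spo2_values=(65.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0),
        hr_values=(80.0, 100.0, 120.0, 130.0),
    )


def enumerate_grid(grid: GridSpec) -> list[SimSetting]:
    """Settings in protocol order: %T slowest, then %MOD, then SpO₂, with HR
    innermost; each list ascending."""
    settings = []
    for t in sorted(grid.t_values):
        for mod in sorted(grid.mod_values):
            for spo2 in sorted(grid.spo2_values):
                for hr in sorted(grid.hr_values):
                    settings.append(SimSetting(t, mod, spo2, hr))
    return settings


def make_sensor_bank(
    n_sensors: int = 7,
    gain_spread_sd: float = 0.005,
    noise_sigma: float = 2e-4,
    master_seed: int = 0,
    quantization_step: float = 0.0,
) -> list[SensorModel]:
    """Draw a bank of distinct virtual finger sensors.

    Per-channel AC gains come from a normal law centered at 1 with sd
    ``gain_spread_sd``; all sensors share the detector noise floor
    ``noise_sigma``.  Child noise seeds are derived deterministically from
    ``master_seed`` so the bank is reproducible.
    """
    if n_sensors < 1:
        raise ValidationError("n_sensors must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(master_seed))
    gains = 1.0 + gain_spread_sd * rng.standard_normal((n_sensors, 2))
    seeds = rng.integers(0, 2**31, size=n_sensors)
    return [
        SensorModel(
            sensor_id=i + 1,
            gain_red=float(gains[i, 0]),
            gain_ir=float(gains[i, 1]),
            noise_sigma=float(noise_sigma),
            quantization_step=float(quantization_step),
            rng_seed=int(seeds[i]),
        )
        for i in range(n_sensors)
    ]


@dataclass(frozen=True)
class SynthConfig:
    """Signal-synthesis parameters shared by every sweep combination."""

    duration_s: float = DEFAULT_DURATION
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE
    template_label: str = "child_nsr"
    dc_ratio: float = 1.0
    curve: CalibrationCurve = field(default_factory=CalibrationCurve)

    def make_template(self) -> PulseTemplate:
        return make_pulse_template(self.template_label, self.sample_rate_hz)


@dataclass(frozen=True)
class SweepRecord:
    """Outcome of one (setting × profile × sensor) combination."""

    setting: SimSetting
    profile_name: str
    sensor_id: int
    n_valid: int
    n_total: int
    mean_signed_error: float
    mean_abs_error: float


def _setting_sensor_seed(master_seed: int, setting: SimSetting, sensor_id: int) -> int:
    # keyed on the setting's identity (not its position in the enumeration),
    # so reordering the sweep cannot change any record
    key = (
        int(master_seed),
        int(round(setting.t_pct * 1e6)),
        int(round(setting.mod_pct * 1e6)),
        int(round(setting.spo2_pct * 1e6)),
        int(round(setting.hr_bpm * 1e6)),
        int(sensor_id),
    )
    return int(np.random.SeedSequence(key).generate_state(1)[0] % 2**31)


def run_sweep(
    grid: GridSpec,
    profiles: list[DeviceProfile],
    sensors: list[SensorModel],
    synth: SynthConfig | None = None,
    master_seed: int = 0,
    settings: list[SimSetting] | None = None,
) -> list[SweepRecord]:
    """Execute the full protocol: every setting × sensor × profile.

    One clean signal is synthesized per setting, corrupted once per sensor
    (with a per-(setting, sensor) noise seed derived from ``master_seed``
    and the setting's identity), and shared across all profiles — both
    devices see the same stimulus.  Per-combination failures are captured
    in the record (``n_valid = 0``) and never abort the sweep.  An explicit
    ``settings`` order overrides the grid enumeration (results are
    order-independent; useful for splitting or spot-checking a sweep).
    """
    if not profiles or not sensors:
        raise ValidationError("profiles and sensors must be non-empty")
    if synth is None:
        synth = SynthConfig()
    template = synth.make_template()
    if settings is None:
        settings = enumerate_grid(grid)
    records: list[SweepRecord] = []
    for i_setting, setting in enumerate(settings):
        try:
            clean = synthesize_optical_signal(
                setting,
                template=template,
                curve=synth.curve,
                duration=synth.duration_s,
                sample_rate=synth.sample_rate_hz,
                dc_ratio=synth.dc_ratio,
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("synthesis failed at %s: %s", setting, exc)
            clean = None
        for sensor in sensors:
            corrupted = None
            if clean is not None:
                seeded = replace(
                    sensor,
                    rng_seed=_setting_sensor_seed(master_seed, setting, sensor.sensor_id),
                )
                try:
                    corrupted = apply_sensor_model(clean, seeded)
                except Exception as exc:  # pragma: no cover - defensive
                    logger.warning("sensor model failed at %s: %s", setting, exc)
            for profile in profiles:
                records.append(
                    _measure_record(corrupted, setting, profile, sensor.sensor_id)
                )
        if (i_setting + 1) % 50 == 0:
            logger.info("sweep progress: %d/%d settings", i_setting + 1, len(settings))
    return records


def _measure_record(
    signal: OpticalSignal | None,
    setting: SimSetting,
    profile: DeviceProfile,
    sensor_id: int,
) -> SweepRecord:
    if signal is None:
        return SweepRecord(setting, profile.name, sensor_id, 0, 0, float("nan"), float("nan"))
    try:
        readings = run_estimator(signal, profile)
    except Exception as exc:
        logger.warning(
            "estimation failed (%s, sensor %d, %s): %s", profile.name, sensor_id, setting, exc
        )
        return SweepRecord(setting, profile.name, sensor_id, 0, 0, float("nan"), float("nan"))
    errors = np.array(
        [r.spo2_pct - setting.spo2_pct for r in readings if r.valid], dtype=float
    )
    n_total = len(readings)
    n_valid = errors.size
    if n_valid == 0:
        return SweepRecord(setting, profile.name, sensor_id, 0, n_total, float("nan"), float("nan"))
    return SweepRecord(
        setting=setting,
        profile_name=profile.name,
        sensor_id=sensor_id,
        n_valid=int(n_valid),
        n_total=int(n_total),
        mean_signed_error=float(errors.mean()),
        mean_abs_error=float(np.abs(errors).mean()),
    )


def records_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    """Long-format results table, one record per row, fixed column order."""
    return pd.DataFrame(
        {
            "t_pct": [r.setting.t_pct for r in records],
            "mod_pct": [r.setting.mod_pct for r in records],
            "spo2_pct": [r.setting.spo2_pct for r in records],
            "hr_bpm": [r.setting.hr_bpm for r in records],
            "profile": [r.profile_name for r in records],
            "sensor_id": [r.sensor_id for r in records],
            "n_valid": [r.n_valid for r in records],
            "n_total": [r.n_total for r in records],
            "mean_signed_error": [r.mean_signed_error for r in records],
            "mean_abs_error": [r.mean_abs_error for r in records],
        },
        columns=SWEEP_COLUMNS,
    )
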