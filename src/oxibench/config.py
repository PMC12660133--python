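"""Run configuration: a single structured-text (YAML) file drives a session.

The configuration validates fully before any computation and a serialized
copy is written next to the outputs for provenance; all randomness flows
from the single ``master_seed`` it records.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .bench_protocol import GridSpec, SynthConfig, default_grid
from .errors import ValidationError
from .ppg_synth import CalibrationCurve
from .virtual_oximeter import DeviceProfile

__all__ = ["RunConfig", "default_run_config", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything one sweep needs: grid, synthesis, sensors, profiles, seed."""

    grid: GridSpec = field(default_factory=default_grid)
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_sensors: int = 7
    gain_spread_sd: float = 0.005
    noise_sigma: float = 2e-4
    quantization_step: float = 0.0
    profiles: tuple[DeviceProfile, ...] = ()
    master_seed: int = 42

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValidationError("n_sensors must be >= 1")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.gain_spread_sd < 0:
            raise ValidationError("gain_spread_sd must be >= 0")
        if not self.profiles:
            from .virtual_oximeter import PROFILE_NAIVE, PROFILE_ROBUST

            object.__setattr__(self, "profiles", (PROFILE_ROBUST, PROFILE_NAIVE))
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValidationError("profile names must be unique")


def default_run_config() -> RunConfig:
    """The shipped benchmark: full grid, 7 sensors, robust + naive profiles."""
    return RunConfig()


def _curve_to_dict(curve: CalibrationCurve) -> dict:
    return {
        "intercept": curve.intercept,
        "slope": curve.slope,
        "quad": curve.quad,
        "r_min": curve.r_min,
        "r_max": curve.r_max,
    }


def _config_to_dict(config: RunConfig) -> dict:
    return {
        "grid": {
            "t_pct": list(config.grid.t_values),
            "mod_pct": list(config.grid.mod_values),
            "spo2_pct": list(config.grid.spo2_values),
            "hr_bpm": list(config.grid.hr_values),
        },
        "synthesis": {
            "duration_s": config.synth.duration_s,
            "sample_rate_hz": config.synth.sample_rate_hz,
            "template": config.synth.template_label,
            "dc_ratio": config.synth.dc_ratio,
        },
        "calibration": _curve_to_dict(config.synth.curve),
        "sensors": {
            "n_sensors": config.n_sensors,
            "gain_spread_sd": config.gain_spread_sd,
            "noise_sigma": config.noise_sigma,
            "quantization_step": config.quantization_step,
        },
        "profiles": [
            {
                "name": p.name,
                "estimator": p.estimator,
                "window_s": p.window_s,
                "step_s": p.step_s,
                "settle_s": p.settle_s,
                "smoothing": p.smoothing,
            }
            for p in config.profiles
        ],
        "master_seed": config.master_seed,
    }


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ValidationError(f"missing required config field {context}.{key}")
    return mapping[key]


def _config_from_dict(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ValidationError("config root must be a mapping")
    grid_d = _require(data, "grid", "config")
    grid = GridSpec(
        t_values=tuple(_require(grid_d, "t_pct", "grid")),
        mod_values=tuple(_require(grid_d, "mod_pct", "grid")),
        spo2_values=tuple(_require(grid_d, "spo2_pct", "grid")),
        hr_values=tuple(_require(grid_d, "hr_bpm", "grid")),
    )
    cal = data.get("calibration", {})
    curve = CalibrationCurve(
        intercept=float(cal.get("intercept", 110.0)),
        slope=float(cal.get("slope", -25.0)),
        quad=float(cal.get("quad", 0.0)),
        r_min=float(cal.get("r_min", 0.1)),
        r_max=float(cal.get("r_max", 4.0)),
    )
    synth_d = data.get("synthesis", {})
    synth = SynthConfig(
        duration_s=float(synth_d.get("duration_s", 45.0)),
        sample_rate_hz=float(synth_d.get("sample_rate_hz", 125.0)),
        template_label=str(synth_d.get("template", "child_nsr")),
        dc_ratio=float(synth_d.get("dc_ratio", 1.0)),
        curve=curve,
    )
    sensors_d = data.get("sensors", {})
    profiles = tuple(
        DeviceProfile(
            name=str(_require(p, "name", "profiles[]")),
            estimator=str(_require(p, "estimator", "profiles[]")),
            window_s=float(p.get("window_s", 8.0)),
            step_s=float(p.get("step_s", 1.0)),
            settle_s=float(p.get("settle_s", 10.0)),
            smoothing=float(p.get("smoothing", 0.3)),
            curve=curve,
        )
        for p in data.get("profiles", [])
    )
    return RunConfig(
        grid=grid,
        synth=synth,
        n_sensors=int(sensors_d.get("n_sensors", 7)),
        gain_spread_sd=float(sensors_d.get("gain_spread_sd", 0.005)),
        noise_sigma=float(sensors_d.get("noise_sigma", 2e-4)),
        quantization_step=float(sensors_d.get("quantization_step", 0.0)),
        profiles=profiles,
        master_seed=int(data.get("master_seed", 42)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Read and fully validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return _config_from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a run configuration (the provenance copy)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
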