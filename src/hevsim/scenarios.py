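"""Scenario configuration: validated YAML schema and the preset library.

A Scenario fully specifies a simulation run: ventilator settings, patient
mechanics and effort, buffer/valve hardware configuration, sensor noise,
timing, and scheduled maneuvers (occlusion holds and setting changes).
Validation is fail-fast -- unknown keys are rejected, every violated field
is enumerated -- because these are clinical-style settings.

The preset registry reproduces the standard bench-test matrices: the
MHRA-style nominal patient, the compliance/resistance patient grid, the
trigger-qualification matrix (delta-P x effort), the leak series, the FIO2
step program and the pressurization sweep.
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import control as ctl
from . import patient as pat
from .pneumatics import FO2_AIR

__all__ = [
    "Scenario",
    "ScenarioValidationError",
    "preset",
    "list_presets",
    "load_scenario",
    "save_scenario",
]


class ScenarioValidationError(ValueError):
    """Scenario failed validation; message enumerates every violated field."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SettingsConfig(_Model):
    mode: Literal["PC_AC", "PC_AC_PRVC", "PC_PSV", "CPAP"] = "PC_AC"
    delta_p: float = 15.0
    peep: float = 5.0
    rise_preset: Literal["fast", "normal", "slow"] = "fast"
    respiratory_rate: float = 12.0
    inhale_time: float = 1.0
    pause_time: float = 0.0
    trigger_threshold: float = Field(0.5, ge=0.2, le=20.0)
    fio2_target: float = Field(FO2_AIR, ge=FO2_AIR, le=1.0)
    prvc_target_vt: float = 450.0
    prvc_max_step: float = 3.0
    psv_cycle_fraction: float = 0.25
    max_inhale_time: float = 3.0
    alarm_limits: dict[str, float] = Field(default_factory=dict)

    def build(self) -> ctl.VentSettings:
        limits = ctl.AlarmLimits(**self.alarm_limits)
        kw = self.model_dump(exclude={"alarm_limits"})
        return ctl.VentSettings(alarm_limits=limits, **kw)


class LungConfig(_Model):
    compliance: float = Field(50.0, gt=0)          # ml/cmH2O
    resistance: float = Field(5.0, ge=0)           # cmH2O/(l/s)
    leak: Union[Literal["none", "weak", "medium", "strong"], float] = "none"
    frc_offset: float = 2000.0                     # ml

    def build(self) -> pat.LungParams:
        leak = self.leak if isinstance(self.leak, float) else pat.leak_preset(self.leak)
        return pat.LungParams(
            compliance=self.compliance,
            resistance=self.resistance,
            leak_conductance=leak,
            frc_offset=self.frc_offset,
        )


class EffortConfig(_Model):
    p01: float = Field(0.0, ge=0)                  # cmH2O
    inhale_duration: float = Field(1.0, gt=0)      # s
    respiratory_rate: float = 12.0                 # efforts/min
    release_time: float = Field(0.3, ge=0)
    first_onset: float = 3.0
    start_times: list[float] = Field(default_factory=list)

    def build(self) -> pat.EffortProfile:
        return pat.EffortProfile(
            p01=self.p01,
            inhale_duration=self.inhale_duration,
            respiratory_rate=self.respiratory_rate,
            release_time=self.release_time,
            first_onset=self.first_onset,
            start_times=tuple(self.start_times),
        )


class BufferConfig(_Model):
    """Buffer and valve hardware configuration.

    Conductances in (l/min)/mbar referenced to outlet conditions; pressures
    mbar gauge.  Defaults: a 25 l buffer filled to 200 mbar holds about
    5 l (ambient-equivalent) above atmosphere -- enough to feed the worst
    supported breath (high inspiratory pressure plus a strong 1 s
    spontaneous effort on a compliant lung) while staying above the 45
    cmH2O maximum airway target, and a 500 ml breath still produces a
    well-resolved ~20 mbar drop for the volume estimator.
    """

    volume: float = Field(25.0, gt=0)              # l
    target_pressure: float = Field(200.0, gt=0)    # mbar gauge
    supply_pressure_air: float = Field(2000.0, gt=0)  # mbar gauge
    supply_pressure_o2: float = Field(2000.0, gt=0)
    conductance_air_in: float = Field(0.25, ge=0)
    conductance_o2_in: float = Field(0.25, ge=0)
    conductance_inhale: float = Field(2.0, ge=0)
    conductance_exhale: float = Field(60.0, ge=0)
    conductance_purge: float = Field(12.0, ge=0)
    actuator_tau: float = Field(0.005, ge=0)       # s, proportional inhale valve
    actuator_tau_onoff: float = Field(0.002, ge=0)  # s, solenoid on/off valves


class NoiseConfig(_Model):
    pressure_sigma: float = Field(0.1, ge=0)       # cmH2O
    flow_sigma: float = Field(0.3, ge=0)           # l/min
    o2_sensor_sigma: float = Field(0.005, ge=0)    # O2 fraction
    seed: Optional[int] = 0

    @model_validator(mode="after")
    def _seed_required(self) -> "NoiseConfig":
        if (self.pressure_sigma > 0 or self.flow_sigma > 0 or self.o2_sensor_sigma > 0) \
                and self.seed is None:
            raise ValueError("a seed is mandatory when any noise sigma is > 0")
        return self


class ManeuverConfig(_Model):
    """Scheduled intervention.

    inspiratory_hold: extend the end-inspiratory occluded pause of the first
    breath whose pause starts at/after `time` by `duration` (plateau
    measurement).  expiratory_hold: occlude at end-exhalation before the
    next breath after `time` for `duration` (intrinsic PEEP).  set_change:
    assign `value` to the ventilator setting `field` at `time`.
    """

    type: Literal["inspiratory_hold", "expiratory_hold", "set_change"]
    time: float = Field(ge=0)
    duration: float = Field(0.5, gt=0)
    field: Optional[str] = None
    value: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ManeuverConfig":
        if self.type == "set_change":
            allowed = {"fio2_target", "delta_p", "peep", "trigger_threshold",
                       "respiratory_rate", "prvc_target_vt"}
            if self.field not in allowed:
                raise ValueError(f"set_change field must be one of {sorted(allowed)}")
            if self.value is None:
                raise ValueError("set_change requires a value")
        return self


class Scenario(_Model):
    """Complete, validated description of one simulation run."""

    version: int = 1
    name: str = "custom"
    settings: SettingsConfig = Field(default_factory=SettingsConfig)
    lung: LungConfig = Field(default_factory=LungConfig)
    effort: EffortConfig = Field(default_factory=EffortConfig)
    buffer: BufferConfig = Field(default_factory=BufferConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    duration: float = Field(60.0, ge=0)            # s
    dt: float = Field(0.001, gt=0, le=0.01)        # physics timestep [s]
    control_period: float = Field(0.01, gt=0)      # control loop period [s]
    maneuvers: list[ManeuverConfig] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check_timing(self) -> "Scenario":
        ratio = self.control_period / self.dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("dt must divide control_period")
        return self

    @classmethod
    def create(cls, **kw) -> "Scenario":
        try:
            return cls(**kw)
        except ValidationError as e:
            raise ScenarioValidationError(str(e)) from None


def load_scenario(path) -> Scenario:
    """Load and validate a YAML scenario file."""
    with open(path) as f:
        data = yaml.safe_load(f)
    if not isinstance(data, dict):
        raise ScenarioValidationError(f"{path}: top level must be a mapping")
    return Scenario.create(**data)


def save_scenario(scenario: Scenario, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(scenario.model_dump(), f, sort_keys=False)


# ---------------------------------------------------------------------------
# Preset library


def _no_noise() -> dict:
    return {"pressure_sigma": 0.0, "flow_sigma": 0.0, "o2_sensor_sigma": 0.0, "seed": 0}


def _mhra_nominal(**kw) -> Scenario:
    """Nominal MHRA-style patient: C=50 ml/cmH2O, R=5 cmH2O/(l/s)."""
    base = dict(
        name="mhra_nominal",
        settings={"mode": "PC_AC", "delta_p": 10.0, "peep": 5.0, "rise_preset": "fast",
                  "respiratory_rate": 12.0, "inhale_time": 1.5, "pause_time": 0.5},
        lung={"compliance": 50.0, "resistance": 5.0},
        duration=60.0,
    )
    base.update(kw)
    return Scenario.create(**base)


def _patient_grid(compliance: float = 50.0, resistance: float = 5.0, **kw) -> Scenario:
    """One cell of the C 10-100 ml/cmH2O x R 5-50 cmH2O/(l/s) grid."""
    if not (10.0 <= compliance <= 100.0 and 5.0 <= resistance <= 50.0):
        raise ValueError("patient_grid spans C in [10,100] ml/cmH2O, R in [5,50] cmH2O/(l/s)")
    base = dict(
        name=f"patient_grid_C{compliance:g}_R{resistance:g}",
        settings={"mode": "PC_AC", "delta_p": 15.0, "peep": 5.0, "rise_preset": "normal",
                  "respiratory_rate": 12.0, "inhale_time": 1.5, "pause_time": 0.5},
        lung={"compliance": compliance, "resistance": resistance},
        noise=_no_noise(),
        duration=30.0,
    )
    base.update(kw)
    return Scenario.create(**base)


def _table1_matrix(delta_p: float = 20.0, effort: str = "high", peep: float = 0.0,
                   **kw) -> Scenario:
    """Trigger-qualification cell: spontaneous efforts against PC-A/C.

    Efforts are 1 s ramps at P0.1 = 2 (low) or 4 (high) cmH2O every 5 s
    (12/min); the mandatory rate is a 10/min backup so every steady-state
    breath is patient-triggered; trigger threshold 0.5 l/min.
    """
    if delta_p not in (10.0, 15.0, 20.0, 25.0):
        raise ValueError("table1_matrix delta_p must be one of 10, 15, 20, 25 cmH2O")
    if effort not in ("low", "high"):
        raise ValueError("table1_matrix effort must be 'low' or 'high'")
    base = dict(
        name=f"table1_dp{delta_p:g}_{effort}",
        settings={"mode": "PC_AC", "delta_p": delta_p, "peep": peep, "rise_preset": "fast",
                  "respiratory_rate": 10.0, "inhale_time": 1.0, "pause_time": 0.0,
                  "trigger_threshold": 0.5},
        lung={"compliance": 50.0, "resistance": 5.0},
        effort={"p01": 2.0 if effort == "low" else 4.0, "inhale_duration": 1.0,
                "respiratory_rate": 12.0, "first_onset": 3.0},
        noise=_no_noise(),
        duration=62.0,
    )
    base.update(kw)
    return Scenario.create(**base)


def _leak_series(leak: str = "none", **kw) -> Scenario:
    """Trigger robustness against leaks: dP=20, PEEP 0, high effort."""
    sc = _table1_matrix(delta_p=20.0, effort="high", peep=0.0, **kw)
    sc.lung.leak = leak
    sc.name = f"leak_series_{leak}"
    return sc


def _fio2_program(**kw) -> Scenario:
    """O2 mixing program: FIO2 stepped to 0.95, held, then down to 0.50 at
    a respiratory rate of 15/min."""
    base = dict(
        name="fio2_program",
        settings={"mode": "PC_AC", "delta_p": 10.0, "peep": 5.0, "rise_preset": "fast",
                  "respiratory_rate": 15.0, "inhale_time": 1.0, "pause_time": 0.0},
        lung={"compliance": 50.0, "resistance": 5.0},
        noise=_no_noise(),
        duration=250.0,
        maneuvers=[
            {"type": "set_change", "time": 5.0, "field": "fio2_target", "value": 0.95},
            {"type": "set_change", "time": 125.0, "field": "fio2_target", "value": 0.50},
        ],
    )
    base.update(kw)
    return Scenario.create(**base)


def _pressurization_sweep(target: float = 25.0, **kw) -> Scenario:
    """One target of the 15-45 cmH2O sweep on the 20 ml/cmH2O, R=5 patient
    with a 1.5 s inhalation followed by a 0.5 s occluded pause."""
    if not (15.0 <= target <= 45.0):
        raise ValueError("pressurization_sweep target must lie within [15, 45] cmH2O")
    peep = 5.0
    base = dict(
        name=f"pressurization_sweep_{target:g}",
        settings={"mode": "PC_AC", "delta_p": target - peep, "peep": peep,
                  "rise_preset": "fast", "respiratory_rate": 12.0,
                  "inhale_time": 1.5, "pause_time": 0.5},
        lung={"compliance": 20.0, "resistance": 5.0},
        noise=_no_noise(),
        duration=12.0,
    )
    base.update(kw)
    return Scenario.create(**base)


_PRESETS = {
    "mhra_nominal": _mhra_nominal,
    "patient_grid": _patient_grid,
    "table1_matrix": _table1_matrix,
    "leak_series": _leak_series,
    "fio2_program": _fio2_program,
    "pressurization_sweep": _pressurization_sweep,
}


def list_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str, **kw) -> Scenario:
    """Build a preset Scenario; grid presets take cell parameters, e.g.
    preset("table1_matrix", delta_p=20, effort="high")."""
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(list_presets())}"
        ) from None
    return factory(**kw)
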