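"""Single-compartment mechanical patient (test-lung equivalent).

A linear one-compartment lung: elastic alveolar compartment with compliance
C behind an airway resistance R, an optional circuit/mask leak at the airway,
and a scripted spontaneous-effort generator parameterized by the occlusion
pressure P0.1 (airway pressure 100 ms after effort onset), the standard
bedside index of inspiratory drive.  Provides the ground-truth effort-onset
times against which trigger metrics are computed.

Clinical units at this surface: pressures in cmH2O (gauge), volumes in ml,
flows in l/min, compliance ml/cmH2O, resistance cmH2O/(l/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

__all__ = [
    "LungParams",
    "EffortProfile",
    "LungState",
    "effort_pressure",
    "lung_step",
    "leak_preset",
    "LEAK_PRESETS",
]

# Conductances in (l/min)/cmH2O chosen so the strong setting leaks about
# 10 l/min at a PEEP of 5 cmH2O -- a clinically plausible heavy mask leak.
LEAK_PRESETS = {"none": 0.0, "weak": 0.5, "medium": 1.0, "strong": 2.0}


def leak_preset(level: str) -> float:
    """Map a leak preset name to a conductance [(l/min)/cmH2O]."""
    try:
        return LEAK_PRESETS[level]
    except KeyError:
        raise ValueError(
            f"unknown leak level {level!r}; choose from {sorted(LEAK_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class LungParams:
    """Mechanical parameters of the single-compartment lung.

    compliance       : [ml/cmH2O], > 0
    resistance       : [cmH2O/(l/s)], >= 0 (0 is rejected at step time when a
                       pressure gradient exists -- flow would be unbounded)
    leak_conductance : airway-to-atmosphere leak [(l/min)/cmH2O]
    frc_offset       : relaxed (FRC) volume reference [ml]; lung volume above
                       FRC is bounded below by -frc_offset
    """

    compliance: float
    resistance: float
    leak_conductance: float = 0.0
    frc_offset: float = 2000.0

    def __post_init__(self) -> None:
        if self.compliance <= 0:
            raise ValueError("compliance must be > 0")
        if self.resistance < 0:
            raise ValueError("resistance must be >= 0")
        if self.leak_conductance < 0:
            raise ValueError("leak_conductance must be >= 0")


@dataclass(frozen=True)
class EffortProfile:
    """Scripted spontaneous inspiratory effort.

    Each effort is a muscle-pressure ramp at the constant rate -(p01/0.1)
    cmH2O/s (so the pressure 100 ms in is exactly -P0.1) sustained for
    inhale_duration, followed by a linear release back to zero over
    release_time.  Onsets come from start_times if given, otherwise from a
    regular schedule at respiratory_rate starting at first_onset.
    """

    p01: float = 0.0
    inhale_duration: float = 1.0
    respiratory_rate: float = 12.0
    release_time: float = 0.3
    first_onset: float = 2.0
    start_times: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p01 < 0:
            raise ValueError("p01 must be >= 0")
        if self.inhale_duration <= 0:
            raise ValueError("inhale_duration must be > 0")
        if self.release_time < 0:
            raise ValueError("release_time must be >= 0")
        st = tuple(self.start_times)
        if any(b <= a for a, b in zip(st, st[1:])):
            raise ValueError("start_times must be strictly increasing")
        object.__setattr__(self, "start_times", st)

    def onsets(self, duration: float) -> tuple[float, ...]:
        """Effort onset times within [0, duration)."""
        if self.p01 == 0.0:
            return ()
        if self.start_times:
            return tuple(t for t in self.start_times if t < duration)
        if self.respiratory_rate <= 0:
            return ()
        period = 60.0 / self.respiratory_rate
        out, t = [], self.first_onset
        while t < duration:
            out.append(t)
            t += period
        return tuple(out)


def effort_pressure(profile: EffortProfile, t_since_onset: float) -> float:
    """Muscle pressure [cmH2O, <= 0] at a time since effort onset.

    Ramp at -(p01/0.1) cmH2O/s for inhale_duration, then a linear release
    back to 0 over release_time; 0 outside the effort.  Pure function.
    """
    if t_since_onset < 0:
        raise ValueError("t_since_onset must be >= 0")
    if profile.p01 == 0.0:
        return 0.0
    rate = profile.p01 / 0.1  # cmH2O/s
    ti = profile.inhale_duration
    if t_since_onset <= ti:
        return -rate * t_since_onset
    depth = rate * ti
    if profile.release_time == 0.0:
        return 0.0
    tr = t_since_onset - ti
    if tr >= profile.release_time:
        return 0.0
    return -depth * (1.0 - tr / profile.release_time)


@dataclass
class LungState:
    """Instantaneous state of the lung.

    volume_above_frc  : [ml]
    muscle_pressure   : [cmH2O], <= 0 during inspiratory effort
    alveolar_pressure : [cmH2O gauge] = volume/compliance + muscle_pressure
    airway_flow       : [l/min], positive into the patient (last step's flow)
    """

    volume_above_frc: float = 0.0
    muscle_pressure: float = 0.0
    alveolar_pressure: float = 0.0
    airway_flow: float = 0.0


def _lung_step_raw(
    volume_ml: float,
    p_mus: float,
    compliance: float,
    resistance: float,
    frc_offset: float,
    airway_pressure: float,
    dt: float,
) -> tuple[float, float, float]:
    """Advance volume by one step; plain floats for the hot loop.

    Returns (volume_ml, alveolar_pressure, airway_flow_lps).  The airway
    leak lives at the circuit node and is handled by the caller.
    """
    p_alv = volume_ml / compliance + p_mus
    flow_lps = (airway_pressure - p_alv) / resistance  # l/s
    volume_ml += flow_lps * 1000.0 * dt
    if volume_ml < -frc_offset:
        volume_ml = -frc_offset
    p_alv = volume_ml / compliance + p_mus
    return volume_ml, p_alv, flow_lps


def lung_step(
    state: LungState,
    params: LungParams,
    airway_pressure: float,
    dt: float,
    muscle_pressure: float | None = None,
) -> LungState:
    """Integrate the equation of motion over one timestep.

    airway_flow = (P_aw - P_alv)/R drives the volume; the alveolar pressure
    is then recomputed from the elastic relation plus muscle pressure.  The
    leak (conductance * P_aw, to atmosphere) is upstream of the lung and does
    not enter the volume balance here.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p_mus = state.muscle_pressure if muscle_pressure is None else muscle_pressure
    if params.resistance == 0.0:
        p_alv0 = state.volume_above_frc / params.compliance + p_mus
        if not math.isclose(airway_pressure, p_alv0, abs_tol=1e-12):
            raise ValueError(
                "resistance = 0 with an airway-alveolar pressure gradient is "
                "ill-conditioned (unbounded flow)"
            )
        return replace(state, muscle_pressure=p_mus, alveolar_pressure=p_alv0, airway_flow=0.0)
    v, p_alv, flow_lps = _lung_step_raw(
        state.volume_above_frc,
        p_mus,
        params.compliance,
        params.resistance,
        params.frc_offset,
        airway_pressure,
        dt,
    )
    return LungState(
        volume_above_frc=v,
        muscle_pressure=p_mus,
        alveolar_pressure=p_alv,
        airway_flow=flow_lps * 60.0,
    )
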