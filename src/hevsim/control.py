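"""Ventilator control: breathing-loop FSM, PID pressurization, triggering,
O2-mixing scheduler and the safety (alarm) loop.

The breathing loop is a finite state machine: the buffer is purged/filled to
its target pressure while the patient exhales, then a breath is started on a
mandatory timer or a patient trigger; during inhalation a PID controller
drives the proportional inhale valve to hold the set inspiratory pressure,
and an optional end-inspiratory pause occludes the circuit for plateau
measurement.  Patient triggering is flow-based: once the exhale flow has
decayed to 10% of its peak the trigger window opens, and a breath starts
when the measured flow exceeds a regression baseline by the set threshold.

Pressures at this surface are cmH2O gauge (patient side) and mbar gauge
(buffer side); flows are l/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .pneumatics import FO2_AIR, GasState, P_AMBIENT

__all__ = [
    "Mode",
    "Phase",
    "VentSettings",
    "AlarmLimits",
    "PidState",
    "pid_update",
    "GAIN_PRESETS",
    "FsmState",
    "ValveCommands",
    "SensorSnapshot",
    "fsm_step",
    "TriggerDecision",
    "inhale_trigger_check",
    "exhale_cycle_check",
    "RefillAction",
    "o2_plan_refill",
    "AlarmEvent",
    "BreathStats",
    "SafetyMonitor",
    "safety_check",
]


class Mode(str, Enum):
    PC_AC = "PC_AC"
    PC_AC_PRVC = "PC_AC_PRVC"
    PC_PSV = "PC_PSV"
    CPAP = "CPAP"


class Phase(str, Enum):
    STANDBY = "STANDBY"
    BUFFER_PURGE = "BUFFER_PURGE"
    BUFFER_FILL_AIR = "BUFFER_FILL_AIR"
    BUFFER_FILL_O2 = "BUFFER_FILL_O2"
    PRE_INHALE = "PRE_INHALE"
    INHALE = "INHALE"
    PAUSE = "PAUSE"
    EXHALE = "EXHALE"
    EXHALE_FILL = "EXHALE_FILL"


# Phases in which the inhale trigger may fire (refractory during INHALE and
# PAUSE so a breath cannot double-trigger).
TRIGGER_ARMED_PHASES = frozenset(
    {Phase.EXHALE, Phase.EXHALE_FILL, Phase.BUFFER_PURGE, Phase.BUFFER_FILL_AIR,
     Phase.BUFFER_FILL_O2, Phase.PRE_INHALE}
)


@dataclass(frozen=True)
class AlarmLimits:
    """Clinician alarm limits; each pair must satisfy min < max."""

    pressure_min: float = 2.0     # cmH2O
    pressure_max: float = 50.0
    vt_min: float = 100.0         # ml
    vt_max: float = 1000.0
    fio2_min: float = 0.18
    fio2_max: float = 1.0
    rate_min: float = 4.0         # breaths/min
    rate_max: float = 40.0

    def __post_init__(self) -> None:
        for name in ("pressure", "vt", "fio2", "rate"):
            lo = getattr(self, f"{name}_min")
            hi = getattr(self, f"{name}_max")
            if not lo < hi:
                raise ValueError(f"alarm limits {name}: min ({lo}) must be < max ({hi})")


@dataclass(frozen=True)
class VentSettings:
    """Clinician-facing ventilator settings.

    delta_p is the inspiratory pressure above PEEP; the hard safety ceiling
    delta_p + peep <= 50 cmH2O is enforced at construction.
    """

    mode: Mode = Mode.PC_AC
    delta_p: float = 15.0          # cmH2O above PEEP
    peep: float = 5.0              # cmH2O
    rise_preset: str = "fast"      # fast | normal | slow
    respiratory_rate: float = 12.0  # breaths/min (mandatory / backup rate)
    inhale_time: float = 1.0       # s
    pause_time: float = 0.0        # s (occluded end-inspiratory pause)
    trigger_threshold: float = 0.5  # l/min, in [0.2, 20]
    fio2_target: float = FO2_AIR
    prvc_target_vt: float = 450.0  # ml (PRVC only)
    prvc_max_step: float = 3.0     # cmH2O max per-breath delta_p adjustment
    psv_cycle_fraction: float = 0.25
    max_inhale_time: float = 3.0   # s, PSV backup cycling
    alarm_limits: AlarmLimits = field(default_factory=AlarmLimits)

    def __post_init__(self) -> None:
        if isinstance(self.mode, str) and not isinstance(self.mode, Mode):
            object.__setattr__(self, "mode", Mode(self.mode))
        if not (0.2 <= self.trigger_threshold <= 20.0):
            raise ValueError("trigger_threshold must be within [0.2, 20] l/min")
        if self.delta_p < 0 or self.peep < 0:
            raise ValueError("delta_p and peep must be >= 0")
        if self.delta_p + self.peep > 50.0:
            raise ValueError("delta_p + peep exceeds the 50 cmH2O safety ceiling")
        if not (FO2_AIR <= self.fio2_target <= 1.0):
            raise ValueError("fio2_target must be in [0.21, 1]")
        if self.rise_preset not in GAIN_PRESETS:
            raise ValueError(f"unknown rise_preset {self.rise_preset!r}")
        if self.respiratory_rate <= 0:
            raise ValueError("respiratory_rate must be > 0")
        if self.inhale_time <= 0 or self.pause_time < 0:
            raise ValueError("inhale_time must be > 0 and pause_time >= 0")

    @property
    def target_pressure(self) -> float:
        """Inspiratory pressure target above atmosphere [cmH2O]."""
        return self.peep + self.delta_p

    @property
    def breath_period(self) -> float:
        return 60.0 / self.respiratory_rate


# ---------------------------------------------------------------------------
# PID


@dataclass(frozen=True)
class PidState:
    """Discrete PID with derivative-on-measurement and integral clamping.

    Gains act on a pressure error in cmH2O and produce a valve opening in
    [0, 1]; the integral term is conditionally accumulated (no windup while
    the output is saturated in the direction of the error).
    """

    kp: float
    ki: float
    kd: float
    integral: float = 0.0
    last_measurement: Optional[float] = None
    out_min: float = 0.0
    out_max: float = 1.0


# Rise-time presets: (kp, ki, kd, setpoint ramp [s]).  The PID gains were
# tuned with scripts/tune_pid.py; the inspiratory setpoint additionally ramps
# linearly from PEEP to the target over the preset's ramp time (the standard
# way pressure controllers realize a clinician-selectable rise time), so the
# nominal lung (C=50 ml/cmH2O, R=5 cmH2O/(l/s)) reaches 95% of its plateau in
# about 50 / 150 / 300 ms.
GAIN_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "fast": (0.02, 1.8, 0.0, 0.0),
    "normal": (0.02, 1.8, 0.0, 0.15),
    "slow": (0.02, 1.8, 0.0, 0.30),
}


def pid_for_preset(preset: str) -> PidState:
    kp, ki, kd, _ = GAIN_PRESETS[preset]
    return PidState(kp=kp, ki=ki, kd=kd)


def rise_ramp_for_preset(preset: str) -> float:
    """Setpoint ramp duration [s] of a rise-time preset."""
    return GAIN_PRESETS[preset][3]


def pid_update(
    pid: PidState, setpoint: float, measurement: float, dt: float
) -> tuple[float, PidState]:
    """One PID step; returns (opening command in [out_min, out_max], state)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    error = setpoint - measurement
    if pid.last_measurement is None or pid.kd == 0.0:
        deriv = 0.0
    else:
        deriv = -(measurement - pid.last_measurement) / dt
    u = pid.kp * error + pid.ki * pid.integral + pid.kd * deriv
    integral = pid.integral
    if (u >= pid.out_max and error > 0) or (u <= pid.out_min and error < 0):
        pass  # saturated in the error's direction: hold the integral
    else:
        integral += error * dt
    u = min(max(u, pid.out_min), pid.out_max)
    return u, replace(pid, integral=integral, last_measurement=measurement)


# ---------------------------------------------------------------------------
# Inhale trigger


@dataclass(frozen=True)
class TriggerDecision:
    decision: bool
    window_open: bool
    baseline: float
    corrected_flow: float
    insufficient_history: bool = False


def _regression_baseline(window: np.ndarray, steps_ahead: float) -> float:
    """Least-squares line over `window`, extrapolated `steps_ahead` past its
    last sample."""
    m = window.shape[0]
    x_mean = 0.5 * (m - 1)
    w_mean = float(window.mean())
    x = np.arange(m, dtype=float)
    sxx = m * (m * m - 1.0) / 12.0
    slope = float(np.dot(x - x_mean, window) / sxx)
    return w_mean + slope * (m - 1 + steps_ahead - x_mean)


def inhale_trigger_check(
    flow_history: Sequence[float] | np.ndarray,
    dt: float,
    threshold: float,
    peak_exhale_flow: float,
    window_open: bool,
    regression_window: float = 0.5,
    guard: float = 0.02,
    window_fraction: float = 0.10,
) -> TriggerDecision:
    """Flow-trigger decision on the most recent sensor samples.

    The trigger window opens at the first sample whose magnitude has decayed
    to `window_fraction` (10%) of the peak exhale flow of the current
    exhalation.  The expected (baseline) flow at the current instant is the
    value of a least-squares line fitted over the trailing
    `regression_window`, excluding the most recent `guard` interval; the
    measured flow (averaged over the guard interval, which the fit excludes)
    is compared against baseline + threshold.

    flow_history: uniformly sampled proximal flow [l/min], most recent last.
    peak_exhale_flow: most negative flow seen this exhalation [l/min].
    """
    if not (0.2 <= threshold <= 20.0):
        raise ValueError("threshold must be within [0.2, 20] l/min")
    flow = np.asarray(flow_history, dtype=float)
    if flow.size == 0:
        return TriggerDecision(False, window_open, 0.0, 0.0, insufficient_history=True)
    current = float(flow[-1])
    if not window_open and peak_exhale_flow < 0.0:
        if abs(current) <= window_fraction * abs(peak_exhale_flow):
            window_open = True
    n_guard = max(1, int(round(guard / dt)))
    n_reg = int(round(regression_window / dt))
    if flow.size < n_guard + n_reg:
        return TriggerDecision(False, window_open, 0.0, 0.0, insufficient_history=True)
    window = flow[-(n_guard + n_reg):-n_guard]
    # the measured flow is averaged over the guard interval, so the baseline
    # is evaluated at that average's centroid: a purely linear flow trend
    # then never looks like an effort
    baseline = _regression_baseline(window, (n_guard + 1) / 2.0)
    smoothed = float(flow[-n_guard:].mean())
    corrected = smoothed - baseline
    decision = bool(window_open and corrected > threshold)
    return TriggerDecision(decision, window_open, baseline, corrected)


def exhale_cycle_check(
    current_flow: float,
    peak_inspiratory_flow: float,
    time_in_inhale: float,
    settings: VentSettings,
) -> bool:
    """PSV cycling to exhalation.

    True when the inspiratory flow has decayed below psv_cycle_fraction of
    its peak, or when the backup maximum inhale time has elapsed.
    """
    if time_in_inhale >= settings.max_inhale_time:
        return True
    if peak_inspiratory_flow <= 0.0:
        return False
    return current_flow < settings.psv_cycle_fraction * peak_inspiratory_flow


# ---------------------------------------------------------------------------
# O2 mixing scheduler


@dataclass(frozen=True)
class RefillAction:
    """Plan for the coming buffer refill.

    kind: "fill" (sequential O2 then air partial-pressure increments),
    "purge_then_fill_o2" or "purge_then_fill_air" (depressurize to ambient
    first, for set-point steps unreachable within a single refill).
    dp_o2/dp_air are the partial-pressure increments [Pa] to add after any
    purge; predicted_fo2 is the post-fill mole fraction.
    """

    kind: str
    dp_o2: float
    dp_air: float
    predicted_fo2: float


def _fill_split(p_start: float, fo2_start: float, p_target: float, fio2_target: float):
    """O2/air partial-pressure split moving post-fill fo2 maximally toward
    the target (clipped to the achievable range)."""
    dp = max(p_target - p_start, 0.0)
    if dp == 0.0:
        return 0.0, 0.0, fo2_start, 0.0
    need = (fio2_target * p_target - fo2_start * p_start - FO2_AIR * dp) / (1.0 - FO2_AIR)
    dp_o2 = min(max(need, 0.0), dp)
    dp_air = dp - dp_o2
    fo2 = (fo2_start * p_start + 1.0 * dp_o2 + FO2_AIR * dp_air) / p_target
    return dp_o2, dp_air, fo2, need


def o2_plan_refill(
    buffer: GasState,
    fio2_target: float,
    ambient: GasState,
    target_pressure_abs: float,
) -> RefillAction:
    """Plan the air/O2 increments for the coming refill.

    Computes the partial-pressure split that moves the post-fill O2 fraction
    maximally toward fio2_target; when the target cannot be approached within
    a plain refill (the required O2 increment exceeds, or the required air
    increment falls below, what a full single-species refill achieves), the
    buffer is first purged to ambient pressure and refilled from there --
    upward steps with pure O2 first, downward steps with air first.
    """
    if not (FO2_AIR <= fio2_target <= 1.0):
        raise ValueError("fio2_target must be in [0.21, 1]")
    p_now = buffer.pressure_abs
    fo2_now = buffer.fo2
    p_t = target_pressure_abs
    dp_o2, dp_air, fo2, _need = _fill_split(p_now, fo2_now, p_t, fio2_target)
    # a plain refill is "enough" when its clipped split lands within a
    # fraction-scale tolerance of the target; otherwise purge to ambient
    # first so the next fill swaps a much larger share of the contents
    if abs(fo2 - fio2_target) <= 1e-6:
        return RefillAction("fill", dp_o2, dp_air, fo2)
    dp_o2p, dp_airp, fo2p, _ = _fill_split(
        ambient.pressure_abs, fo2_now, p_t, fio2_target
    )
    kind = "purge_then_fill_o2" if fo2 < fio2_target else "purge_then_fill_air"
    return RefillAction(kind, dp_o2p, dp_airp, fo2p)


# ---------------------------------------------------------------------------
# Breathing-loop FSM


@dataclass
class FsmState:
    """Breathing-loop finite state machine state."""

    phase: Phase = Phase.STANDBY
    phase_entry_time: float = 0.0
    breath_index: int = 0
    trigger_window_open: bool = False
    peak_exhale_flow: float = 0.0     # l/min, most negative this exhalation
    peak_inspiratory_flow: float = 0.0
    last_inhale_start: float = -math.inf
    next_mandatory_time: float = 0.0
    last_trigger_type: str = "timed"
    # refill bookkeeping for the current fill sequence
    refill_plan: Optional[RefillAction] = None
    fill_o2_until: float = 0.0        # absolute buffer pressure thresholds [Pa]
    fill_air_until: float = 0.0

    def enter(self, phase: Phase, clock: float) -> None:
        self.phase = phase
        self.phase_entry_time = clock


@dataclass(frozen=True)
class SensorSnapshot:
    """Sensor readings handed to the control loop (possibly noisy)."""

    airway_pressure: float        # cmH2O gauge
    buffer_pressure_abs: float    # Pa absolute
    flow: float                   # l/min, proximal, +ve into patient
    fo2: float                    # buffer O2 fraction (calculated)
    trigger_fired: bool = False
    psv_cycle: bool = False


@dataclass(frozen=True)
class ValveCommands:
    air_in: float = 0.0
    o2_in: float = 0.0
    inhale: float = 0.0
    exhale: float = 0.0
    purge: float = 0.0
    inhale_pid_active: bool = False
    occluded: bool = False  # end-inspiratory / pre-inhale occlusion


def buffer_usable(p_abs: float, target_abs: float, fraction: float = 0.90) -> bool:
    """A breath may start once the buffer holds `fraction` of its gauge
    refill target."""
    return p_abs - P_AMBIENT >= fraction * (target_abs - P_AMBIENT)


def fsm_step(
    fsm: FsmState,
    sensors: SensorSnapshot,
    settings: VentSettings,
    clock: float,
    buffer_target_abs: float,
    hold_extension: float = 0.0,
) -> tuple[FsmState, ValveCommands]:
    """Advance the breathing-loop FSM by one control period.

    Mutates and returns `fsm` together with the valve command set for the
    coming period.  `buffer_target_abs` is the refill target [Pa absolute];
    `hold_extension` extends the current occlusion (pause / pre-inhale) for
    scheduled plateau and intrinsic-PEEP maneuvers.
    """
    mode = settings.mode

    if mode is Mode.CPAP:
        # Input valves held open, PID regulates a constant pressure; the
        # exhale path relieves above the CPAP level.
        if fsm.phase is not Phase.INHALE:
            fsm.enter(Phase.INHALE, clock)
        return fsm, ValveCommands(air_in=1.0, o2_in=0.0, exhale=1.0, inhale_pid_active=True)

    def start_inhale(trigger_type: str) -> None:
        fsm.breath_index += 1
        fsm.last_inhale_start = clock
        fsm.next_mandatory_time = clock + settings.breath_period
        fsm.peak_inspiratory_flow = 0.0
        fsm.last_trigger_type = trigger_type
        fsm.enter(Phase.INHALE, clock)

    phase = fsm.phase
    t_in = clock - fsm.phase_entry_time

    if phase is Phase.STANDBY:
        fsm.enter(Phase.BUFFER_FILL_O2, clock)
        fsm.next_mandatory_time = clock
        phase = fsm.phase

    mandatory_due = clock >= fsm.next_mandatory_time and mode is not Mode.PC_PSV
    triggered = sensors.trigger_fired and phase in TRIGGER_ARMED_PHASES

    if phase in (Phase.BUFFER_PURGE, Phase.BUFFER_FILL_O2, Phase.BUFFER_FILL_AIR):
        plan = fsm.refill_plan
        if phase is Phase.BUFFER_PURGE:
            if sensors.buffer_pressure_abs <= P_AMBIENT * 1.002:
                base = sensors.buffer_pressure_abs
                fsm.fill_o2_until = base + (plan.dp_o2 if plan else 0.0)
                fsm.fill_air_until = buffer_target_abs
                fsm.enter(Phase.BUFFER_FILL_O2, clock)
        elif phase is Phase.BUFFER_FILL_O2:
            if sensors.buffer_pressure_abs >= min(fsm.fill_o2_until, buffer_target_abs):
                nxt = Phase.BUFFER_FILL_AIR if fsm.breath_index == 0 else Phase.EXHALE_FILL
                fsm.enter(nxt, clock)
        if fsm.phase is Phase.BUFFER_FILL_AIR:
            if sensors.buffer_pressure_abs >= buffer_target_abs:
                fsm.enter(Phase.EXHALE, clock)
        # a breath may start from any refill phase once the buffer is usable
        if triggered or mandatory_due:
            if buffer_usable(sensors.buffer_pressure_abs, buffer_target_abs):
                start_inhale("patient" if triggered else "timed")

    elif phase is Phase.PRE_INHALE:
        occl = t_in < hold_extension
        if not occl and (triggered or mandatory_due):
            start_inhale("patient" if triggered else "timed")
        else:
            return fsm, ValveCommands(exhale=0.0 if occl else 1.0, occluded=occl)

    elif phase is Phase.INHALE:
        done = t_in >= settings.inhale_time
        if mode is Mode.PC_PSV and sensors.psv_cycle:
            done = True
        if done:
            if settings.pause_time + hold_extension > 0.0:
                fsm.enter(Phase.PAUSE, clock)
            else:
                _begin_exhale(fsm, sensors, clock)

    elif phase is Phase.PAUSE:
        if t_in >= settings.pause_time + hold_extension:
            _begin_exhale(fsm, sensors, clock)

    elif phase in (Phase.EXHALE, Phase.EXHALE_FILL):
        if phase is Phase.EXHALE_FILL and sensors.buffer_pressure_abs >= buffer_target_abs:
            fsm.enter(Phase.EXHALE, clock)
        if triggered or mandatory_due:
            if phase is Phase.EXHALE or buffer_usable(sensors.buffer_pressure_abs,
                                                      buffer_target_abs):
                start_inhale("patient" if triggered else "timed")

    return fsm, _commands_for(fsm.phase)


def _begin_exhale(fsm: FsmState, sensors: SensorSnapshot, clock: float) -> None:
    """Leave inhalation: open the exhale path and start the refill sequence."""
    fsm.peak_exhale_flow = 0.0
    fsm.trigger_window_open = False
    plan = fsm.refill_plan
    if plan is not None and plan.kind != "fill":
        fsm.enter(Phase.BUFFER_PURGE, clock)
    else:
        base = sensors.buffer_pressure_abs
        dp_o2 = plan.dp_o2 if plan else 0.0
        fsm.fill_o2_until = base + dp_o2
        # an O2 sub-fill below 1 Pa is not worth cycling the solenoid for
        fsm.enter(Phase.BUFFER_FILL_O2 if dp_o2 > 1.0 else Phase.EXHALE_FILL, clock)


_PHASE_COMMANDS = {
    Phase.STANDBY: ValveCommands(),
    Phase.BUFFER_PURGE: ValveCommands(exhale=1.0, purge=1.0),
    Phase.BUFFER_FILL_O2: ValveCommands(exhale=1.0, o2_in=1.0),
    Phase.BUFFER_FILL_AIR: ValveCommands(exhale=1.0, air_in=1.0),
    Phase.PRE_INHALE: ValveCommands(exhale=1.0),
    Phase.INHALE: ValveCommands(inhale_pid_active=True),
    Phase.PAUSE: ValveCommands(occluded=True),  # all valves closed: occlusion
    # during idle exhalation the PID valve regulates PEEP from the buffer
    # side; an inspiratory effort dips the airway below PEEP and the PID
    # supplies the flow the proximal sensor detects (the trigger signal)
    Phase.EXHALE: ValveCommands(exhale=1.0, inhale_pid_active=True),
    Phase.EXHALE_FILL: ValveCommands(exhale=1.0, air_in=1.0),
}


def _commands_for(phase: Phase) -> ValveCommands:
    return _PHASE_COMMANDS[phase]


# ---------------------------------------------------------------------------
# Safety loop


@dataclass(frozen=True)
class AlarmEvent:
    kind: str
    priority: str
    raised_at: float
    cleared_at: Optional[float] = None


@dataclass(frozen=True)
class BreathStats:
    """Per-breath summary handed to the safety loop."""

    vt_inhaled: float           # ml
    vt_exhaled: float           # ml
    peak_pressure: float        # cmH2O
    rate: float                 # measured breaths/min
    fio2: float
    target_reached: bool


_PRIORITIES = {
    "pressure_high": "high",
    "pressure_low": "high",
    "vt_high": "medium",
    "vt_low": "medium",
    "fio2_out_of_range": "medium",
    "rate_out_of_range": "medium",
    "obstruction": "high",
    "leakage": "medium",
    "supply_failure": "high",
}


class SafetyMonitor:
    """Alarm generation with persistence debouncing.

    A continuous (sensor-level) condition must hold for at least
    `debounce` seconds before its alarm raises; breath-level conditions
    (obstruction, leakage, volume, rate) raise on the breath that exhibits
    them.  Alarms clear when their condition disappears.
    """

    def __init__(self, limits: AlarmLimits, debounce: float = 0.1,
                 leak_fraction: float = 0.5, obstruction_vt: float = 20.0):
        self.limits = limits
        self.debounce = debounce
        self.leak_fraction = leak_fraction
        self.obstruction_vt = obstruction_vt
        self._pending: dict[str, float] = {}
        self._active: dict[str, AlarmEvent] = {}
        self.events: list[AlarmEvent] = []

    def _set(self, kind: str, condition: bool, now: float, debounced: bool) -> None:
        if condition:
            if kind in self._active:
                return
            if debounced:
                start = self._pending.setdefault(kind, now)
                if now - start < self.debounce:
                    return
            ev = AlarmEvent(kind, _PRIORITIES[kind], raised_at=now)
            self._active[kind] = ev
            self.events.append(ev)
        else:
            self._pending.pop(kind, None)
            if kind in self._active:
                ev = self._active.pop(kind)
                idx = self.events.index(ev)
                self.events[idx] = replace(ev, cleared_at=now)

    def check(
        self,
        airway_pressure: float,
        now: float,
        breath: Optional[BreathStats] = None,
        supply_ok: bool = True,
    ) -> list[AlarmEvent]:
        """Evaluate alarm conditions; returns currently active alarms sorted
        by priority (high first)."""
        lim = self.limits
        self._set("pressure_high", airway_pressure > lim.pressure_max, now, True)
        self._set("pressure_low", airway_pressure < lim.pressure_min, now, True)
        self._set("supply_failure", not supply_ok, now, True)
        if breath is not None:
            self._set("vt_high", breath.vt_inhaled > lim.vt_max, now, False)
            self._set("vt_low", breath.vt_inhaled < lim.vt_min, now, False)
            self._set(
                "fio2_out_of_range",
                not (lim.fio2_min <= breath.fio2 <= lim.fio2_max),
                now, False,
            )
            self._set(
                "rate_out_of_range",
                not (lim.rate_min <= breath.rate <= lim.rate_max),
                now, False,
            )
            self._set(
                "obstruction",
                breath.target_reached and breath.vt_inhaled < self.obstruction_vt,
                now, False,
            )
            self._set(
                "leakage",
                breath.vt_inhaled > 0
                and breath.vt_exhaled < self.leak_fraction * breath.vt_inhaled,
                now, False,
            )
        order = {"high": 0, "medium": 1, "low": 2}
        return sorted(self._active.values(), key=lambda e: order[e.priority])


def safety_check(
    monitor: SafetyMonitor,
    airway_pressure: float,
    now: float,
    breath: Optional[BreathStats] = None,
    supply_ok: bool = True,
) -> list[AlarmEvent]:
    """Functional wrapper over SafetyMonitor.check (one control period)."""
    return monitor.check(airway_pressure, now, breath=breath, supply_ok=supply_ok)
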