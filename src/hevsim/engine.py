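"""Fixed-step co-simulation of pneumatics + patient + control.

The physics (valve actuators, airway node balance, lung equation of motion,
buffer mole/energy balance) advances at the physics timestep (default
1 ms); the breathing-loop FSM, PID and safety loop execute at the control
period (default 10 ms), mirroring an embedded control rate.  The flow
trigger is evaluated at the sensor rate so that trigger latency reflects
the detection physics rather than control-grid aliasing; a detection
invokes the control step immediately, like an interrupt.

The airway is treated as a volumeless node: with linear valve and lung
conductances the airway pressure is the closed-form solution of the node
flow balance each step.  The exhale path is an ideal threshold (PEEP
relief) element in series with the on/off exhale valve.  Reported flows and
volumes are referenced to ambient conditions; the buffer is accounted in
moles, adiabatically while it delivers (inlets closed) and isothermally
while it refills.  The buffer valves are interlocked so that only one of
them moves gas at a time: every fill or purge is then a pure-species
segment whose pressure endpoints carry the full mole balance, which is what
makes the event-replay FIO2 calculation exact.

Everything is deterministic given the scenario and its noise seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import control as ctl
from .control import (
    FsmState,
    Mode,
    Phase,
    SafetyMonitor,
    SensorSnapshot,
    o2_plan_refill,
    pid_for_preset,
    pid_update,
)
from .estimation import BreathRecord, FillEvent, O2Sensor, buffer_delivered_volume
from .io import TimeSeries, PHASE_CODES
from .pneumatics import (
    CMH2O,
    FO2_AIR,
    GAMMA,
    GasState,
    LPM,
    MBAR,
    P_AMBIENT,
    R_GAS,
    T_AMBIENT,
    BufferDepletionError,
    _buffer_step_raw,
)
from .scenarios import Scenario

__all__ = ["run_scenario", "SimResult", "NumericalError"]

_ARMED = ctl.TRIGGER_ARMED_PHASES
_FILL_PHASES = frozenset(
    {Phase.BUFFER_PURGE, Phase.BUFFER_FILL_O2, Phase.BUFFER_FILL_AIR, Phase.EXHALE_FILL}
)
ALARM_KINDS = tuple(ctl._PRIORITIES)


class NumericalError(RuntimeError):
    """Simulation state became non-finite; message carries the timestamp."""


@dataclass
class SimResult:
    """Everything a run produces."""

    timeseries: Optional[TimeSeries]
    breaths: list[BreathRecord]
    alarms: list[ctl.AlarmEvent]
    effort_onsets: tuple[float, ...]
    pause_windows: list[tuple[float, float]] = field(default_factory=list)
    hold_windows: list[tuple[float, float]] = field(default_factory=list)
    refill_times: list[float] = field(default_factory=list)
    fill_events: list[FillEvent] = field(default_factory=list)
    fio2_calculated: float = FO2_AIR
    buffer_fo2: float = FO2_AIR
    final_settings: Optional[ctl.VentSettings] = None
    # mole audit: n(start) + moles_in - moles_out must equal n(end)
    buffer_moles_start: float = 0.0
    buffer_moles_end: float = 0.0
    buffer_moles_in: float = 0.0
    buffer_moles_out: float = 0.0


def run_scenario(scenario: Scenario, record: bool = True) -> SimResult:
    """Run a scenario to completion.

    record=False skips the time-series logging consumer (per-breath records
    and alarms are still produced), which is also how the independence of
    the breathing loop from logging is verified.
    """
    dt = scenario.dt
    n_steps = int(round(scenario.duration / dt))
    settings = scenario.settings.build()
    lungp = scenario.lung.build()
    effort = scenario.effort.build()
    bc = scenario.buffer
    if n_steps == 0:
        return SimResult(
            timeseries=TimeSeries.empty(dt) if record else None,
            breaths=[], alarms=[], effort_onsets=(), final_settings=settings,
        )
    cpap = settings.mode is Mode.CPAP

    # --- static SI quantities -------------------------------------------
    v_buf = bc.volume * 1e-3                       # m3
    p_target_abs = P_AMBIENT + bc.target_pressure * MBAR
    p_sup_air = P_AMBIENT + bc.supply_pressure_air * MBAR
    p_sup_o2 = P_AMBIENT + bc.supply_pressure_o2 * MBAR
    c_air = bc.conductance_air_in * LPM / MBAR     # m3/s/Pa
    c_o2 = bc.conductance_o2_in * LPM / MBAR
    c_inh = bc.conductance_inhale * LPM / MBAR
    c_ex = bc.conductance_exhale * LPM / MBAR
    c_pu = bc.conductance_purge * LPM / MBAR
    tau = bc.actuator_tau
    tau_oo = bc.actuator_tau_onoff
    v_alpha = {
        k: (1.0 if tk == 0 else 1.0 - math.exp(-dt / tk))
        for k, tk in (("inh", tau), ("air", tau_oo), ("o2", tau_oo),
                      ("ex", tau_oo), ("pu", tau_oo))
    }

    c_si = lungp.compliance * 1e-6 / CMH2O         # m3/Pa
    if lungp.resistance <= 0:
        raise ValueError("resistance = 0 is an ill-conditioned patient configuration")
    g_lung = 1e-3 / (lungp.resistance * CMH2O)
    g_leak = lungp.leak_conductance * LPM / CMH2O
    frc_si = lungp.frc_offset * 1e-6

    ctrl_every = int(round(scenario.control_period / dt))
    n_guard = max(1, int(round(0.02 / dt)))
    n_reg = int(round(0.5 / dt))
    m = n_reg
    x_mean = 0.5 * (m - 1)
    sxx = m * (m * m - 1.0) / 12.0
    x_eval = m - 1 + (n_guard + 1) / 2.0 - x_mean

    rng = np.random.default_rng(scenario.noise.seed or 0)
    sig_p = scenario.noise.pressure_sigma
    sig_f = scenario.noise.flow_sigma
    noise_p = rng.normal(0.0, sig_p, n_steps) if sig_p > 0 else None
    noise_f = rng.normal(0.0, sig_f, n_steps) if sig_f > 0 else None
    o2_sensor = O2Sensor(sigma=scenario.noise.o2_sensor_sigma,
                         rng=rng if scenario.noise.o2_sensor_sigma > 0 else None)
    o2_alpha = 1.0 - math.exp(-dt / o2_sensor.tau)

    onsets = effort.onsets(scenario.duration)
    onset_idx = 0
    p01_rate = effort.p01 / 0.1 * CMH2O            # Pa/s
    eff_inh = effort.inhale_duration
    eff_rel = effort.release_time
    eff_depth = p01_rate * eff_inh

    # --- mutable state ---------------------------------------------------
    p_buf = float(P_AMBIENT)
    t_buf = float(T_AMBIENT)
    fo2 = FO2_AIR
    v_lung = 0.0                                   # m3 above FRC
    act = dict.fromkeys(("air", "o2", "inh", "ex", "pu"), 0.0)
    cmd = dict.fromkeys(act, 0.0)

    fsm = FsmState()
    pid = pid_for_preset(settings.rise_preset)
    monitor = SafetyMonitor(settings.alarm_limits)
    ambient_state = GasState(P_AMBIENT, v_buf, T_AMBIENT, FO2_AIR)

    flow_hist = np.zeros(n_steps)
    if record:
        tr_p = np.empty(n_steps); tr_pb = np.empty(n_steps)
        tr_vol = np.empty(n_steps); tr_fo2 = np.empty(n_steps)
        tr_oair = np.empty(n_steps); tr_oo2 = np.empty(n_steps)
        tr_oinh = np.empty(n_steps); tr_oex = np.empty(n_steps)
        tr_opu = np.empty(n_steps); tr_phase = np.empty(n_steps, dtype=np.int8)
        tr_pmus = np.empty(n_steps); tr_alarm = np.empty(n_steps, dtype=np.int16)

    S1 = Sx = G = 0.0
    last_pid_t: Optional[float] = None
    alarm_mask = 0

    # per-breath accumulators
    vt_in = vt_ex = 0.0
    peak_flow = peak_p = 0.0
    breath_t0 = 0.0
    cur_breath_index = 0
    cur_trigger_type = "timed"
    p1_cap: Optional[float] = None
    p2_cap: Optional[float] = None
    fio2_at_start = FO2_AIR
    fio2_meas_cap: Optional[float] = None
    plateau: Optional[float] = None
    intrinsic: Optional[float] = None
    pause_samples: list[float] = []
    hold_samples: list[float] = []
    pause_t0: Optional[float] = None
    hold_t0: Optional[float] = None
    prev_breath_start: Optional[float] = None

    breaths: list[BreathRecord] = []
    pause_windows: list[tuple[float, float]] = []
    hold_windows: list[tuple[float, float]] = []
    refill_times: list[float] = []
    refill_t0: Optional[float] = None
    fill_events: list[FillEvent] = []
    fo2_calc = FO2_AIR                             # event-replay mole balance
    seg_open = dict.fromkeys(("air", "o2", "pu"), False)
    seg_p0 = dict.fromkeys(("air", "o2", "pu"), 0.0)

    insp_hold = 0.0
    exp_hold = 0.0
    maneuvers = [{"cfg": mv, "done": False} for mv in scenario.maneuvers]

    def close_breath(now: float) -> None:
        nonlocal prev_breath_start, plateau, intrinsic
        if cur_breath_index == 0:
            return
        vt_b = 0.0
        if p1_cap is not None and p2_cap is not None and p2_cap <= p1_cap:
            vt_b = buffer_delivered_volume(
                p1_cap, T_AMBIENT, p2_cap, v_buf, GAMMA, ambient_state, "adiabatic"
            )
        rate = (60.0 / (breath_t0 - prev_breath_start)
                if prev_breath_start is not None and breath_t0 > prev_breath_start
                else settings.respiratory_rate)
        breaths.append(BreathRecord(
            breath_index=cur_breath_index,
            t_start=breath_t0,
            trigger_type=cur_trigger_type,
            vt_proximal=vt_in,
            vt_buffer=vt_b,
            plateau_pressure=plateau,
            intrinsic_peep=intrinsic,
            fio2_calculated=fio2_at_start,
            fio2_measured=o2_sensor.read() if fio2_meas_cap is None else fio2_meas_cap,
            peak_flow=peak_flow,
            peak_pressure=peak_p,
        ))
        stats = ctl.BreathStats(
            vt_inhaled=vt_in, vt_exhaled=vt_ex, peak_pressure=peak_p,
            rate=rate, fio2=fio2_at_start,
            target_reached=peak_p >= 0.9 * settings.target_pressure,
        )
        monitor.check(peak_p, now, breath=stats)
        prev_breath_start = breath_t0
        plateau = None
        intrinsic = None

    def control_step(i: int, trigger_fired: bool) -> None:
        nonlocal settings, pid, last_pid_t, vt_in, vt_ex, peak_flow, peak_p
        nonlocal breath_t0, cur_breath_index, cur_trigger_type
        nonlocal p1_cap, p2_cap, fio2_at_start, fio2_meas_cap, insp_hold, exp_hold
        nonlocal p_buf, t_buf, refill_t0, pause_t0, hold_t0, alarm_mask
        nonlocal plateau, intrinsic
        now = i * dt
        if not (math.isfinite(p_aw) and math.isfinite(p_buf) and math.isfinite(v_lung)):
            raise NumericalError(f"simulation state became non-finite at t={now:.4f} s")

        for mv in maneuvers:
            cfg = mv["cfg"]
            if mv["done"] or now < cfg.time:
                continue
            if cfg.type == "set_change":
                settings = replace(settings, **{cfg.field: cfg.value})
                mv["done"] = True
            elif cfg.type == "inspiratory_hold":
                insp_hold = cfg.duration
                mv["done"] = True
            elif cfg.type == "expiratory_hold":
                if fsm.phase is Phase.EXHALE and abs(flow_lpm) < 2.0:
                    exp_hold = cfg.duration
                    fsm.enter(Phase.PRE_INHALE, now)
                    mv["done"] = True

        flow_s = flow_hist[i]
        p_aw_s = p_aw / CMH2O + (noise_p[i] if noise_p is not None else 0.0)

        psv_cycle = False
        if settings.mode is Mode.PC_PSV and fsm.phase is Phase.INHALE:
            psv_cycle = ctl.exhale_cycle_check(
                flow_s, peak_flow, now - fsm.phase_entry_time, settings
            )

        if fsm.phase in (Phase.INHALE, Phase.PAUSE) and not cpap:
            fsm.refill_plan = o2_plan_refill(
                GasState(p_buf, v_buf, t_buf, fo2), settings.fio2_target,
                ambient_state, p_target_abs,
            )

        hold = 0.0
        if fsm.phase in (Phase.INHALE, Phase.PAUSE):
            hold = insp_hold
        elif fsm.phase is Phase.PRE_INHALE:
            hold = exp_hold

        sensors = SensorSnapshot(
            airway_pressure=p_aw_s, buffer_pressure_abs=p_buf, flow=flow_s,
            fo2=fo2, trigger_fired=trigger_fired, psv_cycle=psv_cycle,
        )
        prev_phase = fsm.phase
        prev_breath = fsm.breath_index
        ctl.fsm_step(fsm, sensors, settings, now, p_target_abs, hold_extension=hold)
        phase = fsm.phase

        # delivery over: capture the buffer endpoint for the volume
        # calculation, then let the buffer re-equilibrate thermally and
        # re-plan the refill from the fresh state
        if prev_phase is Phase.INHALE and phase is not Phase.INHALE:
            p2_cap = p_buf
            fio2_meas_cap = o2_sensor.read()  # inspired-O2 readout at end-inhale
        if phase not in (Phase.INHALE, Phase.PAUSE) and t_buf != T_AMBIENT:
            p_buf *= T_AMBIENT / t_buf
            t_buf = T_AMBIENT
            if phase in _FILL_PHASES and not cpap:
                fsm.refill_plan = o2_plan_refill(
                    GasState(p_buf, v_buf, t_buf, fo2), settings.fio2_target,
                    ambient_state, p_target_abs,
                )
                ctl._begin_exhale(fsm, replace(sensors, buffer_pressure_abs=p_buf), now)
                phase = fsm.phase

        # occlusion-window bookkeeping (plateau / intrinsic PEEP)
        if phase is Phase.PAUSE and pause_t0 is None:
            pause_t0 = now
            pause_samples.clear()
        if prev_phase is Phase.PAUSE and phase is not Phase.PAUSE and pause_t0 is not None:
            pause_windows.append((pause_t0, now))
            if pause_samples:
                half = pause_samples[len(pause_samples) // 2:]
                plateau = sum(half) / len(half)
            pause_t0 = None
            insp_hold = 0.0
        if phase is Phase.PRE_INHALE and hold > 0 and hold_t0 is None:
            hold_t0 = now
            hold_samples.clear()
        if prev_phase is Phase.PRE_INHALE and phase is not Phase.PRE_INHALE and hold_t0 is not None:
            hold_windows.append((hold_t0, now))
            if hold_samples:
                half = hold_samples[len(hold_samples) // 2:]
                intrinsic = sum(half) / len(half)
            hold_t0 = None
            exp_hold = 0.0

        if phase in _FILL_PHASES and prev_phase not in _FILL_PHASES and prev_breath > 0:
            refill_t0 = now

        if fsm.breath_index != prev_breath:
            close_breath(now)
            if settings.mode is Mode.PC_AC_PRVC and breaths and breaths[-1].vt_proximal > 10.0:
                want = settings.delta_p * (settings.prvc_target_vt / breaths[-1].vt_proximal - 1.0)
                step = min(max(want, -settings.prvc_max_step), settings.prvc_max_step)
                new_dp = min(max(settings.delta_p + step, 1.0), 50.0 - settings.peep)
                settings = replace(settings, delta_p=new_dp)
            breath_t0 = now
            cur_breath_index = fsm.breath_index
            cur_trigger_type = fsm.last_trigger_type
            # pressurization restarts from a closed valve every breath
            pid = replace(pid, integral=0.0, last_measurement=None)
            vt_in = vt_ex = 0.0
            peak_flow = 0.0
            peak_p = 0.0
            p1_cap = p_buf
            p2_cap = None
            fio2_at_start = fo2
            fio2_meas_cap = None

        if cpap:
            c = ctl.ValveCommands(air_in=1.0, exhale=1.0, inhale_pid_active=True)
        else:
            c = ctl._commands_for(phase)
        cmd["ex"] = c.exhale
        cmd["pu"] = c.purge
        cmd["air"] = c.air_in
        cmd["o2"] = c.o2_in
        if c.inhale_pid_active:
            if cpap:
                sp = settings.peep
            elif phase is Phase.EXHALE:
                # PEEP support with a small deadband: the valve engages only
                # on a genuine effort dip, not on sensor noise around PEEP
                sp = settings.peep - 0.1
            else:
                sp = settings.target_pressure
                ramp = ctl.rise_ramp_for_preset(settings.rise_preset)
                t_in = now - fsm.phase_entry_time
                if ramp > 0.0 and t_in < ramp:
                    sp = settings.peep + settings.delta_p * (t_in / ramp)
            if phase is not prev_phase:
                pid = replace(pid, integral=0.0, last_measurement=None)
            dt_pid = scenario.control_period if last_pid_t is None else \
                min(max(now - last_pid_t, dt), scenario.control_period)
            u, pid = pid_update(pid, sp, p_aw_s, dt_pid)
            cmd["inh"] = u
            last_pid_t = now
        else:
            cmd["inh"] = 0.0
            last_pid_t = None

        active = monitor.check(p_aw_s, now)
        mask = 0
        for ev in active:
            mask |= 1 << ALARM_KINDS.index(ev.kind)
        alarm_mask = mask

    # --- main loop -------------------------------------------------------
    p_aw = 0.0
    flow_lpm = 0.0
    n_in_total = 0.0
    n_out_total = 0.0
    n_start = p_buf * v_buf / (R_GAS * t_buf)
    for i in range(n_steps):
        t = i * dt

        # actuators: first-order lag toward command, with a seating snap so
        # a closing valve reaches exactly zero in finite time
        for k in act:
            a = act[k]
            ck = cmd[k]
            a += (ck - a) * v_alpha[k]
            if ck == 0.0 and a < 1e-3:
                a = 0.0
            act[k] = a

        # buffer-valve interlocks: one gas-moving path at a time
        inh_seated = act["inh"] == 0.0 or cpap
        e_o2 = act["o2"] if (act["air"] == 0.0 and act["pu"] == 0.0 and inh_seated) else 0.0
        e_air = act["air"] if (act["o2"] == 0.0 and act["pu"] == 0.0 and inh_seated) else 0.0
        e_pu = act["pu"] if (act["o2"] == 0.0 and act["air"] == 0.0) else 0.0

        # muscle pressure from the effort schedule
        p_mus = 0.0
        if onset_idx < len(onsets):
            ts = t - onsets[onset_idx]
            if ts >= 0.0:
                if ts <= eff_inh:
                    p_mus = -p01_rate * ts
                elif eff_rel > 0.0 and ts < eff_inh + eff_rel:
                    p_mus = -eff_depth * (1.0 - (ts - eff_inh) / eff_rel)
                else:
                    onset_idx += 1

        # airway node balance (Pa gauge)
        p_alv = v_lung / c_si + p_mus
        p_buf_g = p_buf - P_AMBIENT
        peep_g = settings.peep * CMH2O
        g_in = c_inh * act["inh"]
        g_ex = c_ex * act["ex"]
        p_aw = (g_in * p_buf_g + g_lung * p_alv + g_ex * peep_g) / (g_in + g_lung + g_leak + g_ex)
        if g_ex > 0.0 and p_aw < peep_g:
            # PEEP threshold element closed: re-solve without the exhale path
            p_aw = (g_in * p_buf_g + g_lung * p_alv) / (g_in + g_lung + g_leak)
        if g_in > 0.0 and p_buf_g < p_aw:
            # inhale check valve blocks reverse flow
            g_in = 0.0
            p_aw = (g_lung * p_alv + g_ex * peep_g) / (g_lung + g_leak + g_ex)
            if g_ex > 0.0 and p_aw < peep_g:
                p_aw = g_lung * p_alv / (g_lung + g_leak)

        q_lung = (p_aw - p_alv) * g_lung
        q_leak = g_leak * p_aw
        v_lung += q_lung * dt
        if v_lung < -frc_si:
            v_lung = -frc_si

        # buffer mole balance
        p_prev = p_buf
        q_del = g_in * (p_buf_g - p_aw)
        ndot_out = (p_aw + P_AMBIENT) * q_del / (R_GAS * T_AMBIENT) if q_del > 0.0 else 0.0
        ndot_air = ndot_o2 = 0.0
        if e_air > 0.0 and p_sup_air > p_buf:
            ndot_air = p_buf * (c_air * e_air * (p_sup_air - p_buf)) / (R_GAS * t_buf)
        if e_o2 > 0.0 and p_sup_o2 > p_buf:
            ndot_o2 = p_buf * (c_o2 * e_o2 * (p_sup_o2 - p_buf)) / (R_GAS * t_buf)
        if e_pu > 0.0 and p_buf > P_AMBIENT:
            ndot_out += P_AMBIENT * (c_pu * e_pu * (p_buf - P_AMBIENT)) / (R_GAS * T_AMBIENT)
        if ndot_air or ndot_o2 or ndot_out:
            adiab = fsm.phase in (Phase.INHALE, Phase.PAUSE)
            n_in_total += (ndot_air + ndot_o2) * dt
            n_out_total += ndot_out * dt
            p_buf, t_buf, fo2 = _buffer_step_raw(
                p_buf, t_buf, fo2, v_buf, ndot_air, ndot_o2, ndot_out, dt, adiab
            )
            if ndot_out > 0.0 and ndot_air == 0.0 and ndot_o2 == 0.0 and p_buf <= P_AMBIENT:
                if e_pu == 0.0:
                    raise BufferDepletionError(
                        f"buffer depleted at t={t:.3f} s (pressure fell to ambient)"
                    )

        # fill/purge segment bookkeeping at effective-flow boundaries; each
        # closed segment is one pure-species FillEvent
        for k, flowing in (("air", e_air > 0.0), ("o2", e_o2 > 0.0), ("pu", e_pu > 0.0)):
            if flowing and not seg_open[k]:
                seg_open[k] = True
                seg_p0[k] = p_prev
            elif not flowing and seg_open[k]:
                seg_open[k] = False
                p0 = seg_p0[k]
                if k == "pu":
                    fill_events.append(FillEvent("air", p0, p_buf, t_buf, t))
                elif p_buf > p0:
                    fill_events.append(FillEvent(k, p0, p_buf, t_buf, t))
                    purity = 1.0 if k == "o2" else FO2_AIR
                    fo2_calc = (fo2_calc * p0 + purity * (p_buf - p0)) / p_buf

        # fill cutoffs at the sensor rate, anticipating the actuator tail
        if cmd["o2"] > 0.0:
            tail = ndot_o2 * R_GAS * t_buf / v_buf * tau_oo
            if p_buf + tail >= fsm.fill_o2_until:
                cmd["o2"] = 0.0
        if cmd["air"] > 0.0:
            tail = ndot_air * R_GAS * t_buf / v_buf * tau_oo
            if p_buf + tail >= p_target_abs:
                cmd["air"] = 0.0
        if refill_t0 is not None and p_buf >= p_target_abs:
            refill_times.append(t - refill_t0)
            refill_t0 = None

        # sensors (flows referenced to ambient conditions)
        flow_lpm = (q_lung + q_leak) * (p_aw + P_AMBIENT) / P_AMBIENT / LPM
        f_meas = flow_lpm + (noise_f[i] if noise_f is not None else 0.0)
        flow_hist[i] = f_meas
        o2_sensor.value += (fo2 - o2_sensor.value) * o2_alpha

        # rolling sums for the trigger-baseline regression
        G += f_meas
        if i >= n_guard:
            G -= flow_hist[i - n_guard]
            w_new = flow_hist[i - n_guard]
            if i >= n_guard + n_reg:
                w_old = flow_hist[i - n_guard - n_reg]
                Sx += -S1 + w_old + (m - 1) * w_new
                S1 += w_new - w_old
            else:
                Sx += (i - n_guard) * w_new
                S1 += w_new

        # breath accumulators
        phase = fsm.phase
        if phase is Phase.INHALE:
            if flow_lpm > 0.0:
                vt_in += flow_lpm * dt * (1000.0 / 60.0)
                if flow_lpm > peak_flow:
                    peak_flow = flow_lpm
            p_cm = p_aw / CMH2O
            if p_cm > peak_p:
                peak_p = p_cm
        elif flow_lpm < 0.0:
            vt_ex -= flow_lpm * dt * (1000.0 / 60.0)
        if pause_t0 is not None and phase is Phase.PAUSE:
            pause_samples.append(p_aw / CMH2O + (noise_p[i] if noise_p is not None else 0.0))
        if hold_t0 is not None and phase is Phase.PRE_INHALE:
            hold_samples.append(p_aw / CMH2O + (noise_p[i] if noise_p is not None else 0.0))

        # trigger detection at the sensor rate
        trigger = False
        if phase in _ARMED and not cpap:
            if flow_lpm < fsm.peak_exhale_flow:
                fsm.peak_exhale_flow = flow_lpm
            if not fsm.trigger_window_open:
                if fsm.peak_exhale_flow < 0.0:
                    if abs(f_meas) <= 0.10 * abs(fsm.peak_exhale_flow):
                        fsm.trigger_window_open = True
                elif (phase in (Phase.EXHALE, Phase.PRE_INHALE)
                      and t - fsm.phase_entry_time > 0.5):
                    # no exhalation observed yet (start of ventilation):
                    # arm once the circuit has settled
                    fsm.trigger_window_open = True
            if fsm.trigger_window_open and i >= n_guard + n_reg:
                slope = (Sx - x_mean * S1) / sxx
                baseline = S1 / m + slope * x_eval
                corrected = G / n_guard - baseline
                if corrected > settings.trigger_threshold:
                    seated = act["air"] == 0.0 and act["o2"] == 0.0 and act["pu"] == 0.0
                    if seated and ctl.buffer_usable(p_buf, p_target_abs):
                        trigger = True

        if record:
            tr_p[i] = p_aw / CMH2O + (noise_p[i] if noise_p is not None else 0.0)
            tr_pb[i] = (p_buf - P_AMBIENT) / MBAR
            tr_vol[i] = vt_in
            tr_fo2[i] = fo2
            tr_oair[i] = act["air"]; tr_oo2[i] = act["o2"]
            tr_oinh[i] = act["inh"]; tr_oex[i] = act["ex"]; tr_opu[i] = act["pu"]
            tr_phase[i] = PHASE_CODES[phase.value]
            tr_pmus[i] = p_mus / CMH2O
            tr_alarm[i] = alarm_mask

        if trigger or i % ctrl_every == 0:
            control_step(i, trigger)

    # wrap up: close the running breath and any open fill segment
    t_end = n_steps * dt
    for k in ("air", "o2", "pu"):
        if seg_open[k]:
            seg_open[k] = False
            p0 = seg_p0[k]
            if k == "pu":
                fill_events.append(FillEvent("air", p0, p_buf, t_buf, t_end))
            elif p_buf > p0:
                fill_events.append(FillEvent(k, p0, p_buf, t_buf, t_end))
                purity = 1.0 if k == "o2" else FO2_AIR
                fo2_calc = (fo2_calc * p0 + purity * (p_buf - p0)) / p_buf
    close_breath(t_end)

    ts = None
    if record:
        ts = TimeSeries.from_arrays(
            dt=dt,
            time=np.arange(n_steps) * dt,
            p_airway=tr_p, p_buffer=tr_pb, flow=flow_hist.copy(), volume=tr_vol,
            fo2=tr_fo2, o_air=tr_oair, o_o2=tr_oo2, o_inhale=tr_oinh,
            o_exhale=tr_oex, o_purge=tr_opu, phase=tr_phase, p_mus=tr_pmus,
            alarms=tr_alarm,
        )
    return SimResult(
        timeseries=ts,
        breaths=breaths,
        alarms=list(monitor.events),
        effort_onsets=onsets,
        pause_windows=pause_windows,
        hold_windows=hold_windows,
        refill_times=refill_times,
        fill_events=fill_events,
        fio2_calculated=fo2_calc,
        buffer_fo2=fo2,
        final_settings=settings,
        buffer_moles_start=n_start,
        buffer_moles_end=p_buf * v_buf / (R_GAS * t_buf),
        buffer_moles_in=n_in_total,
        buffer_moles_out=n_out_total,
    )
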