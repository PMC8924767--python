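"""PID, FSM transitions, triggering, O2 planning and the safety loop."""

import math

import numpy as np
import pytest

from hevsim.control import (
    AlarmLimits,
    BreathStats,
    FsmState,
    GAIN_PRESETS,
    Mode,
    Phase,
    PidState,
    SafetyMonitor,
    SensorSnapshot,
    VentSettings,
    buffer_usable,
    exhale_cycle_check,
    fsm_step,
    inhale_trigger_check,
    o2_plan_refill,
    pid_update,
    safety_check,
)
from hevsim.pneumatics import FO2_AIR, GasState, P_AMBIENT


class TestPid:
    def test_zero_error_zero_output(self):
        pid = PidState(kp=0.05, ki=0.5, kd=0.0)
        u, _ = pid_update(pid, 20.0, 20.0, 0.01)
        assert u == 0.0

    def test_proportional_saturation(self):
        """kp=0.05, step error 20 -> kp*e = 1.0, exactly at the clamp."""
        pid = PidState(kp=0.05, ki=0.0, kd=0.0)
        u, _ = pid_update(pid, 20.0, 0.0, 0.01)
        assert u == 1.0
        u, _ = pid_update(PidState(kp=0.2, ki=0.0, kd=0.0), 20.0, 0.0, 0.01)
        assert u == 1.0  # saturated

    def test_integral_accumulates_and_clamps(self):
        pid = PidState(kp=0.0, ki=1.0, kd=0.0)
        u, pid = pid_update(pid, 10.0, 0.0, 0.1)
        assert pid.integral == pytest.approx(1.0)
        # saturated output in the error's direction freezes the integral
        for _ in range(100):
            u, pid = pid_update(pid, 10.0, 0.0, 0.1)
        assert u == 1.0
        assert pid.ki * pid.integral <= 1.0 + pid.kp * 10.0 + 1e-9

    def test_derivative_on_measurement(self):
        pid = PidState(kp=0.0, ki=0.0, kd=0.01)
        _, pid = pid_update(pid, 0.0, 0.0, 0.01)
        u, _ = pid_update(pid, 0.0, 1.0, 0.01)  # measurement rising
        assert u == 0.0  # derivative opposes the rise, clamped at 0

    def test_presets_exist(self):
        assert set(GAIN_PRESETS) == {"fast", "normal", "slow"}
        # slower presets have longer setpoint ramps
        assert GAIN_PRESETS["fast"][3] < GAIN_PRESETS["normal"][3] < GAIN_PRESETS["slow"][3]


def _sensors(**kw):
    base = dict(airway_pressure=5.0, buffer_pressure_abs=P_AMBIENT + 20_000.0,
                flow=0.0, fo2=FO2_AIR)
    base.update(kw)
    return SensorSnapshot(**base)


class TestFsm:
    target_abs = P_AMBIENT + 20_000.0

    def test_trigger_starts_breath_from_exhale(self):
        fsm = FsmState()
        fsm.enter(Phase.EXHALE, 10.0)
        fsm.breath_index = 3
        fsm.next_mandatory_time = 15.0
        settings = VentSettings()
        fsm, cmd = fsm_step(fsm, _sensors(trigger_fired=True), settings, 10.5,
                            self.target_abs)
        assert fsm.phase is Phase.INHALE
        assert fsm.breath_index == 4
        assert fsm.last_trigger_type == "patient"
        assert cmd.inhale_pid_active

    def test_zero_pause_skips_to_exhale_fill(self):
        fsm = FsmState()
        fsm.enter(Phase.INHALE, 0.0)
        fsm.breath_index = 1
        settings = VentSettings(inhale_time=1.0, pause_time=0.0)
        fsm, cmd = fsm_step(fsm, _sensors(), settings, 1.01, self.target_abs)
        assert fsm.phase in (Phase.EXHALE_FILL, Phase.BUFFER_FILL_O2)
        assert cmd.exhale == 1.0

    def test_pause_occludes_all_valves(self):
        fsm = FsmState()
        fsm.enter(Phase.INHALE, 0.0)
        fsm.breath_index = 1
        settings = VentSettings(inhale_time=1.0, pause_time=0.5)
        fsm, cmd = fsm_step(fsm, _sensors(), settings, 1.01, self.target_abs)
        assert fsm.phase is Phase.PAUSE
        assert cmd.occluded
        assert cmd.inhale == cmd.exhale == cmd.air_in == cmd.o2_in == 0.0

    def test_no_trigger_during_inhale_refractory(self):
        fsm = FsmState()
        fsm.enter(Phase.INHALE, 0.0)
        fsm.breath_index = 1
        settings = VentSettings(inhale_time=1.0)
        fsm, _ = fsm_step(fsm, _sensors(trigger_fired=True), settings, 0.5,
                          self.target_abs)
        assert fsm.phase is Phase.INHALE
        assert fsm.breath_index == 1

    def test_cpap_holds_inputs_open_and_pid_active(self):
        fsm = FsmState()
        settings = VentSettings(mode=Mode.CPAP, delta_p=0.0, peep=5.0)
        fsm, cmd = fsm_step(fsm, _sensors(), settings, 0.0, self.target_abs)
        assert cmd.air_in == 1.0
        assert cmd.inhale_pid_active
        assert cmd.exhale == 1.0

    def test_buffer_usable_is_gauge_fraction(self):
        target = P_AMBIENT + 20_000.0
        assert buffer_usable(P_AMBIENT + 18_000.0, target)
        assert not buffer_usable(P_AMBIENT + 17_000.0, target)


class TestInhaleTrigger:
    dt = 0.001

    def _history(self, n=600, value=0.0):
        return np.full(n, value)

    def test_window_opens_at_ten_percent_of_peak(self):
        """Peak exhale -60 l/min: the window opens once |flow| <= 6."""
        hist = self._history(value=-6.5)
        d = inhale_trigger_check(hist, self.dt, 0.5, peak_exhale_flow=-60.0,
                                 window_open=False)
        assert not d.window_open
        hist[-1] = -5.9
        d = inhale_trigger_check(hist, self.dt, 0.5, peak_exhale_flow=-60.0,
                                 window_open=False)
        assert d.window_open

    def test_below_threshold_no_trigger(self):
        hist = self._history(value=0.0)
        hist[-20:] = 0.4
        d = inhale_trigger_check(hist, self.dt, 0.5, -60.0, window_open=True)
        assert d.window_open and not d.decision
        assert d.corrected_flow == pytest.approx(0.4, abs=1e-9)

    def test_baseline_correction_enables_trigger(self):
        """A decaying tail gives a negative baseline; flow +0.4 corrected
        against baseline -0.2 clears a 0.5 threshold."""
        n = 600
        t = np.arange(n) * self.dt
        hist = -0.2 + 0.0 * t  # flat baseline at -0.2
        hist[-20:] = 0.4
        d = inhale_trigger_check(hist, self.dt, 0.5, -60.0, window_open=True)
        assert d.baseline == pytest.approx(-0.2, abs=1e-9)
        assert d.corrected_flow == pytest.approx(0.6, abs=1e-9)
        assert d.decision

    def test_regression_tracks_linear_decay(self):
        """The baseline is the least-squares line extrapolated to now, so a
        linear flow trend alone never looks like an effort."""
        n = 1000
        t = np.arange(n) * self.dt
        hist = -30.0 + 25.0 * t  # steady linear recovery
        d = inhale_trigger_check(hist, self.dt, 0.5, -60.0, window_open=True)
        assert d.corrected_flow == pytest.approx(0.0, abs=1e-6)
        assert not d.decision

    def test_insufficient_history_flagged(self):
        d = inhale_trigger_check(np.zeros(100), self.dt, 0.5, -60.0, window_open=True)
        assert d.insufficient_history and not d.decision

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            inhale_trigger_check(np.zeros(600), self.dt, 0.1, -60.0, window_open=True)


class TestExhaleCycle:
    settings = VentSettings(mode=Mode.PC_PSV)

    def test_cycles_below_fraction_of_peak(self):
        assert exhale_cycle_check(14.0, 60.0, 0.5, self.settings)   # 14 < 15

    def test_no_cycle_at_peak(self):
        assert not exhale_cycle_check(60.0, 60.0, 0.5, self.settings)

    def test_backup_time_cycles_regardless(self):
        assert exhale_cycle_check(60.0, 60.0, 3.5, self.settings)


class TestO2Plan:
    ambient = GasState(P_AMBIENT, 0.025, 293.0, FO2_AIR)
    target_abs = P_AMBIENT + 18_000.0

    def test_air_only_at_air_target(self):
        buf = GasState(P_AMBIENT + 5_000.0, 0.025, 293.0, FO2_AIR)
        act = o2_plan_refill(buf, FO2_AIR, self.ambient, self.target_abs)
        assert act.kind == "fill"
        assert act.dp_o2 == pytest.approx(0.0, abs=1e-6)
        assert act.predicted_fo2 == pytest.approx(FO2_AIR)

    def test_unreachable_step_purges_then_fills_o2(self):
        """0.21 -> 0.95 from atmospheric pressure: purge, then pure O2; the
        post-fill fraction is (0.21*1013 + 180)/1193."""
        buf = GasState(101_300.0, 0.01, 293.0, FO2_AIR)
        act = o2_plan_refill(buf, 0.95, GasState(101_300.0, 0.01, 293.0, FO2_AIR),
                             101_300.0 + 18_000.0)
        assert act.kind == "purge_then_fill_o2"
        assert act.dp_air == 0.0
        assert act.predicted_fo2 == pytest.approx((0.21 * 1013 + 180) / 1193, rel=1e-6)

    def test_downward_step_purges_then_fills_air(self):
        buf = GasState(self.target_abs - 2_000.0, 0.025, 293.0, 0.95)
        act = o2_plan_refill(buf, 0.30, self.ambient, self.target_abs)
        assert act.kind == "purge_then_fill_air"

    def test_reachable_step_fills_exactly(self):
        buf = GasState(P_AMBIENT + 10_000.0, 0.025, 293.0, 0.50)
        act = o2_plan_refill(buf, 0.52, self.ambient, self.target_abs)
        assert act.kind == "fill"
        assert act.predicted_fo2 == pytest.approx(0.52, abs=1e-9)
        assert 0.0 <= act.dp_o2 <= self.target_abs - buf.pressure_abs

    def test_invalid_target_rejected(self):
        buf = GasState(P_AMBIENT + 10_000.0, 0.025, 293.0, 0.5)
        with pytest.raises(ValueError):
            o2_plan_refill(buf, 0.1, self.ambient, self.target_abs)


class TestSafetyLoop:
    def test_pressure_high_debounced_then_raised(self):
        mon = SafetyMonitor(AlarmLimits(pressure_max=50.0))
        active = []
        for i in range(25):  # 250 ms above the limit at 10 ms steps
            active = safety_check(mon, 55.0, i * 0.01)
        assert [a.kind for a in active] == ["pressure_high"]
        assert active[0].priority == "high"
        # under the 100 ms persistence no alarm raises
        mon2 = SafetyMonitor(AlarmLimits(pressure_max=50.0))
        for i in range(5):
            active = safety_check(mon2, 55.0, i * 0.01)
        assert active == [] or all(a.kind != "pressure_high" for a in active)

    def test_all_readings_within_limits_is_quiet(self):
        mon = SafetyMonitor(AlarmLimits())
        breath = BreathStats(vt_inhaled=450.0, vt_exhaled=440.0, peak_pressure=20.0,
                             rate=14.0, fio2=0.4, target_reached=True)
        active = safety_check(mon, 20.0, 1.0, breath=breath)
        assert active == []

    def test_leakage_ratio_rule(self):
        """Exhaled volume at 40% of inhaled crosses the 50% leak threshold."""
        mon = SafetyMonitor(AlarmLimits())
        breath = BreathStats(vt_inhaled=500.0, vt_exhaled=200.0, peak_pressure=20.0,
                             rate=14.0, fio2=0.3, target_reached=True)
        active = safety_check(mon, 20.0, 1.0, breath=breath)
        assert "leakage" in [a.kind for a in active]

    def test_obstruction_on_no_volume_at_full_pressure(self):
        mon = SafetyMonitor(AlarmLimits(vt_min=0.5))
        breath = BreathStats(vt_inhaled=5.0, vt_exhaled=5.0, peak_pressure=25.0,
                             rate=14.0, fio2=0.3, target_reached=True)
        active = safety_check(mon, 20.0, 1.0, breath=breath)
        assert "obstruction" in [a.kind for a in active]

    def test_alarm_clears_and_records_interval(self):
        mon = SafetyMonitor(AlarmLimits(pressure_max=50.0))
        for i in range(20):
            safety_check(mon, 60.0, i * 0.01)
        active = safety_check(mon, 20.0, 0.5)
        assert active == []
        ev = mon.events[0]
        assert ev.kind == "pressure_high" and ev.cleared_at == 0.5
        assert ev.raised_at < ev.cleared_at

    def test_priority_sorting(self):
        mon = SafetyMonitor(AlarmLimits(pressure_max=50.0))
        breath = BreathStats(vt_inhaled=500.0, vt_exhaled=100.0, peak_pressure=60.0,
                             rate=14.0, fio2=0.3, target_reached=True)
        for i in range(20):
            active = safety_check(mon, 60.0, i * 0.01, breath=breath if i == 15 else None)
        kinds = [a.priority for a in active]
        assert kinds == sorted(kinds, key={"high": 0, "medium": 1, "low": 2}.get)


class TestVentSettings:
    def test_safety_ceiling(self):
        with pytest.raises(ValueError):
            VentSettings(delta_p=46.0, peep=5.0)

    @pytest.mark.parametrize("kw", [dict(trigger_threshold=0.1),
                                    dict(trigger_threshold=25.0),
                                    dict(fio2_target=0.1),
                                    dict(respiratory_rate=0.0)])
    def test_invalid_settings_rejected(self, kw):
        with pytest.raises(ValueError):
            VentSettings(**kw)

    def test_alarm_limits_well_ordered(self):
        with pytest.raises(ValueError):
            AlarmLimits(pressure_min=60.0, pressure_max=50.0)
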