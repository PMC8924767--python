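"""Tune the PID gain presets for the three rise-time settings.

Simulates steady pressure-control breaths on the nominal lung
(C=50 ml/cmH2O, R=5 cmH2O/(l/s)) for a grid of (kp, ki) gains and reports
the steady-state 95% rise time, overshoot and pause-pressure accuracy, so
the fast/normal/slow presets can be frozen in hevsim.control.GAIN_PRESETS
at roughly 50 / 150 / 300 ms.

Usage: python scripts/tune_pid.py [fast|normal|slow|check]
"""

from __future__ import annotations

import sys

import numpy as np

import hevsim as hs
from hevsim import control


def evaluate(kp: float, ki: float, kd: float = 0.0, preset: str = "fast",
             ramp: float | None = None):
    if ramp is None:
        ramp = control.GAIN_PRESETS[preset][3]
    control.GAIN_PRESETS[preset] = (kp, ki, kd, ramp)
    sc = hs.preset(
        "mhra_nominal",
        settings={"mode": "PC_AC", "delta_p": 20.0, "peep": 5.0,
                  "rise_preset": preset, "respiratory_rate": 12.0,
                  "inhale_time": 1.5, "pause_time": 0.5},
        noise={"pressure_sigma": 0.0, "flow_sigma": 0.0,
               "o2_sensor_sigma": 0.0, "seed": 0},
        duration=30.0,
    )
    res = hs.run_scenario(sc)
    p = res.timeseries.column("p_airway")
    target = 25.0
    rts, overs = [], []
    for b in res.breaths[2:]:
        rt = hs.rise_time(p, sc.dt, b.t_start, target)
        if rt is not None:
            rts.append(rt)
        i0 = int(b.t_start / sc.dt)
        overs.append(p[i0:i0 + 1500].max() / target - 1.0)
    acc = hs.pressure_accuracy(p, sc.dt, res.pause_windows[2:], target)
    return (float(np.mean(rts)) if rts else float("nan"),
            100.0 * float(np.max(overs)), acc.relative_deviation)


def sweep(name: str, kps, kis):
    print(f"--- {name}: rise_ms overshoot% pause_dev%")
    for kp in kps:
        for ki in kis:
            try:
                rt, ov, dev = evaluate(kp, ki, 0.0, name)
                print(f"kp={kp:<7g} ki={ki:<7g} -> {rt:7.1f} ms  {ov:6.2f} %  {dev:5.3f} %")
            except Exception as e:
                print(f"kp={kp:<7g} ki={ki:<7g} -> failed: {e}")


if __name__ == "__main__":
    which = sys.argv[1] if len(sys.argv) > 1 else "check"
    if which == "fast":
        sweep("fast", [0.02, 0.03, 0.045, 0.06, 0.08], [1.0, 1.8, 3.0, 5.0])
    elif which == "normal":
        sweep("normal", [0.005, 0.008, 0.012, 0.02], [0.2, 0.4, 0.7, 1.2])
    elif which == "slow":
        sweep("slow", [0.001, 0.002, 0.004], [0.08, 0.12, 0.16, 0.25])
    else:
        for preset, (kp, ki, kd) in control.GAIN_PRESETS.items():
            rt, ov, dev = evaluate(kp, ki, kd, preset)
            print(f"{preset:<7}: rise {rt:6.1f} ms  overshoot {ov:6.2f} %  pause dev {dev:5.3f} %")
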