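"""Post-hoc waveform analysis: trigger-qualification battery and
pressurization statistics.

The trigger battery quantifies patient-ventilator synchrony from the airway
pressure trace around a known effort onset: time to minimum pressure (TPM),
trigger delay time (TDT, onset to the return of pressure to baseline),
pressure drop (PD), the pressure-time product of the triggering effort
(PTP), and the delivered pressurization over the 300/500 ms after the
trigger delay as a percentage of an ideal square pressurization (PTP300%,
PTP500%).  Pressurization statistics cover pause-phase accuracy relative to
the set target and the 95% rise time.

All integrals are trapezoidal; crossing times are linearly interpolated
between samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TriggerMetrics",
    "PressureAccuracy",
    "trigger_metrics",
    "pressure_accuracy",
    "rise_time",
    "metric_perturbation",
]


@dataclass(frozen=True)
class TriggerMetrics:
    """Trigger-qualification variables for one (or an average of) breaths.

    tpm [ms], tdt [ms], pd [cmH2O], ptp [cmH2O s], ptp300/ptp500 [%].
    tdt is None when the pressure never returned to baseline in the trace.
    """

    tpm: float
    tdt: Optional[float]
    pd: float
    ptp: float
    ptp300: Optional[float]
    ptp500: Optional[float]


@dataclass(frozen=True)
class PressureAccuracy:
    target: float               # cmH2O
    mean_pause_pressure: float  # cmH2O
    relative_deviation: float   # %, >= 0


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t1
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def trigger_metrics(
    pressure_trace: Sequence[float] | np.ndarray,
    dt: float,
    effort_onset: float,
    baseline_pressure: float,
    delta_p_set: float,
    horizon: float = 1.2,
) -> TriggerMetrics:
    """Compute the trigger battery for one breath.

    pressure_trace: uniformly sampled airway pressure [cmH2O] whose time
    origin is t=0; effort_onset is the ground-truth effort start [s] (from
    the patient model); baseline_pressure is the pre-effort baseline (the
    PEEP level), so the definitions work at nonzero PEEP; delta_p_set is the
    set inspiratory pressure above baseline, used for the ideal-PTP
    denominators.  The trace must span at least 1 s past the onset.
    """
    p = np.asarray(pressure_trace, dtype=float)
    i_on = int(round(effort_onset / dt))
    if i_on < 0 or i_on >= p.size:
        raise ValueError("effort_onset lies outside the trace")
    if (p.size - 1 - i_on) * dt < 1.0:
        raise ValueError("trace must span at least 1 s beyond the effort onset")
    i_end = min(p.size, i_on + int(round(horizon / dt)) + 1)
    seg = p[i_on:i_end]
    t = np.arange(seg.size) * dt  # time since onset

    i_min = int(np.argmin(seg))
    p_min = float(seg[i_min])
    tpm = t[i_min]
    pd = max(0.0, baseline_pressure - p_min)

    # first return to baseline after the minimum
    tdt: Optional[float] = None
    above = seg[i_min:] >= baseline_pressure
    if pd == 0.0:
        tdt = tpm
    elif above.any():
        j = int(np.argmax(above))  # first True
        k = i_min + j
        tdt = _interp_crossing(t[k - 1], t[k], seg[k - 1], seg[k], baseline_pressure)

    # PTP: effort area below baseline from onset to TDT
    if tdt is None or tdt == 0.0:
        ptp = 0.0
    else:
        n = int(tdt / dt)
        tt = np.append(t[: n + 1], tdt)
        vv = np.append(seg[: n + 1], baseline_pressure)
        ptp = float(np.trapezoid(baseline_pressure - vv, tt))
        ptp = max(0.0, ptp)

    def _ptp_pct(width: float) -> Optional[float]:
        if tdt is None or delta_p_set <= 0:
            return None
        t1, t2 = tdt, tdt + width
        if t2 > t[-1]:
            return None
        grid = np.arange(np.ceil(t1 / dt), np.floor(t2 / dt) + 1, dtype=int)
        tt = np.concatenate(([t1], grid * dt, [t2]))
        vv = np.interp(tt, t, seg)
        area = float(np.trapezoid(vv - baseline_pressure, tt))
        return 100.0 * area / (delta_p_set * width)

    return TriggerMetrics(
        tpm=tpm * 1e3,
        tdt=None if tdt is None else tdt * 1e3,
        pd=pd,
        ptp=ptp,
        ptp300=_ptp_pct(0.3),
        ptp500=_ptp_pct(0.5),
    )


def pressure_accuracy(
    pressure_trace: Sequence[float] | np.ndarray,
    dt: float,
    pause_windows: Sequence[tuple[float, float]],
    target: float,
) -> PressureAccuracy:
    """Mean pause-phase pressure and its relative deviation from the target.

    pause_windows are (start, end) occlusion intervals in seconds; the mean
    is taken over the final half of each window (the settled part).
    """
    if not pause_windows:
        raise ValueError("at least one pause window is required")
    p = np.asarray(pressure_trace, dtype=float)
    chunks = []
    for t0, t1 in pause_windows:
        i0 = int(round(t0 / dt))
        i1 = int(round(t1 / dt))
        if i0 < 0 or i1 > p.size or i1 <= i0:
            raise ValueError(f"pause window ({t0}, {t1}) lies outside the trace")
        chunks.append(p[(i0 + i1) // 2 : i1])
    mean = float(np.concatenate(chunks).mean())
    dev = 100.0 * abs(mean - target) / target
    return PressureAccuracy(target=target, mean_pause_pressure=mean, relative_deviation=dev)


def rise_time(
    pressure_trace: Sequence[float] | np.ndarray,
    dt: float,
    inhale_start: float,
    target: float,
    fraction: float = 0.95,
) -> Optional[float]:
    """Time [ms] from inhale_start to the first crossing of fraction*target.

    Returns None (undefined) if the trace never crosses the level.
    """
    p = np.asarray(pressure_trace, dtype=float)
    i0 = int(round(inhale_start / dt))
    if i0 < 0 or i0 >= p.size:
        raise ValueError("inhale_start lies outside the trace")
    level = fraction * target
    seg = p[i0:]
    if seg[0] >= level:
        return 0.0
    above = seg >= level
    if not above.any():
        return None
    k = int(np.argmax(above))
    t_cross = _interp_crossing((k - 1) * dt, k * dt, seg[k - 1], seg[k], level)
    return t_cross * 1e3


def metric_perturbation(
    metrics_a: TriggerMetrics, metrics_b: TriggerMetrics
) -> tuple[float, list[str]]:
    """Maximum relative difference [%] over {tpm, tdt, pd, ptp}.

    Metrics with a zero (or undefined) reference value are excluded from the
    maximum and reported in the returned skip list.
    """
    worst = 0.0
    skipped: list[str] = []
    for name in ("tpm", "tdt", "pd", "ptp"):
        a = getattr(metrics_a, name)
        b = getattr(metrics_b, name)
        if a is None or b is None or a == 0.0:
            skipped.append(name)
            continue
        worst = max(worst, 100.0 * abs(a - b) / abs(a))
    return worst, skipped
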