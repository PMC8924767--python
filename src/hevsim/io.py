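"""Time-series container, CSV dialects, and analytic fixture waveforms.

The CSV time-series dialect has a fixed column order and a declared header;
floats are written in round-trip (repr) precision so read(write(ts)) == ts.
The FSM phase is stored as its name and the active alarms as a bitmask over
the alarm kinds (bit i = kind ALARM_KIND_ORDER[i]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "PHASE_CODES",
    "PHASE_NAMES",
    "write_timeseries",
    "read_timeseries",
    "write_breath_table",
    "fixture_waveform",
]

# stable phase <-> code mapping for the compact in-memory representation
PHASE_NAMES = [
    "STANDBY", "BUFFER_PURGE", "BUFFER_FILL_AIR", "BUFFER_FILL_O2",
    "PRE_INHALE", "INHALE", "PAUSE", "EXHALE", "EXHALE_FILL",
]
PHASE_CODES = {name: i for i, name in enumerate(PHASE_NAMES)}

_FLOAT_COLUMNS = [
    "time", "p_airway", "p_buffer", "flow", "volume", "fo2",
    "o_air", "o_o2", "o_inhale", "o_exhale", "o_purge", "p_mus",
]
COLUMNS = _FLOAT_COLUMNS[:11] + ["phase", "p_mus", "alarms"]


@dataclass
class TimeSeries:
    """Uniformly sampled simulation traces.

    Columns: time [s], p_airway [cmH2O], p_buffer [mbar gauge], flow
    [l/min, ambient-referenced, +ve into patient], volume [ml delivered in
    the current breath], fo2 [buffer O2 fraction], valve openings (air-in,
    o2-in, inhale, exhale, purge), phase [FSM phase code], p_mus [cmH2O],
    alarms [active-alarm bitmask].
    """

    df: pd.DataFrame
    dt: float

    @classmethod
    def empty(cls, dt: float) -> "TimeSeries":
        return cls(df=pd.DataFrame({c: [] for c in COLUMNS}), dt=dt)

    @classmethod
    def from_arrays(cls, dt: float, **arrays) -> "TimeSeries":
        df = pd.DataFrame({c: arrays[c] for c in COLUMNS})
        return cls(df=df, dt=dt)

    def __len__(self) -> int:
        return len(self.df)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def phase_names(self) -> np.ndarray:
        return np.array(PHASE_NAMES, dtype=object)[self.df["phase"].to_numpy().astype(int)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return self.dt == other.dt and self.df.equals(other.df)


def write_timeseries(ts: TimeSeries, path) -> None:
    """Write the fixed-column CSV dialect (phase stored by name)."""
    df = ts.df.copy()
    df["phase"] = np.array(PHASE_NAMES, dtype=object)[df["phase"].to_numpy().astype(int)]
    df["alarms"] = df["alarms"].astype(int)
    with open(path, "w") as f:
        f.write(f"# hevsim timeseries v1 dt={ts.dt!r}\n")
        df.to_csv(f, index=False, float_format="%.17g")


def read_timeseries(path) -> TimeSeries:
    """Read a time-series CSV; raises on a malformed header or ragged rows."""
    with open(path) as f:
        first = f.readline()
        if not first.startswith("# hevsim timeseries v1"):
            raise ValueError(f"{path}: missing hevsim timeseries header line")
        try:
            dt = float(first.rsplit("dt=", 1)[1])
        except (IndexError, ValueError):
            raise ValueError(f"{path}: header line carries no parsable dt") from None
        try:
            df = pd.read_csv(f, dtype={"phase": str}, float_precision="round_trip")
        except pd.errors.ParserError as e:
            raise ValueError(f"{path}: malformed CSV: {e}") from None
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COLUMNS]
    if extra:
        raise ValueError(f"{path}: unexpected column(s): {', '.join(extra)}")
    bad = set(df["phase"]) - set(PHASE_NAMES)
    if bad:
        raise ValueError(f"{path}: unknown phase value(s): {sorted(bad)}")
    df["phase"] = df["phase"].map(PHASE_CODES).astype(np.int8)
    df["alarms"] = df["alarms"].astype(np.int16)
    for c in COLUMNS:
        if c not in ("phase", "alarms"):
            df[c] = df[c].astype(np.float64)
    return TimeSeries(df=df[COLUMNS], dt=dt)


def write_breath_table(breaths, path) -> None:
    """Per-breath metric table (CSV)."""
    rows = []
    for b in breaths:
        rows.append({
            "breath_index": b.breath_index,
            "t_start": b.t_start,
            "trigger_type": b.trigger_type,
            "vt_proximal_ml": b.vt_proximal,
            "vt_buffer_ml": b.vt_buffer,
            "plateau_cmH2O": b.plateau_pressure,
            "intrinsic_peep_cmH2O": b.intrinsic_peep,
            "fio2_calculated": b.fio2_calculated,
            "fio2_measured": b.fio2_measured,
            "peak_flow_lpm": b.peak_flow,
            "peak_pressure_cmH2O": b.peak_pressure,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analytic fixture waveforms with closed-form truth attached


@dataclass(frozen=True)
class FixtureWaveform:
    """Sampled analytic trace plus its closed-form reference values."""

    samples: np.ndarray
    dt: float
    truth: dict


def _triangle_dip(depth: float = 2.0, nadir: float = 0.1, ret: float = 0.15,
                  plateau: float = 20.0, baseline: float = 0.0,
                  duration: float = 1.5, dt: float = 0.001) -> FixtureWaveform:
    """Pressure dip falling linearly to -depth at `nadir`, returning to
    baseline at `ret`, then stepping instantly to baseline + plateau."""
    t = np.arange(int(round(duration / dt))) * dt
    p = np.full(t.size, baseline + plateau)
    rise = t <= ret
    p[rise] = baseline - depth * np.minimum(t[rise] / nadir, 1.0)
    fall = (t > nadir) & (t <= ret)
    p[fall] = baseline - depth * (1.0 - (t[fall] - nadir) / (ret - nadir))
    truth = {
        "tpm_ms": nadir * 1e3,
        "tdt_ms": ret * 1e3,
        "pd": depth,
        "ptp": 0.5 * depth * ret,
        # the sampled step spends half a sample ramping 0 -> plateau, so the
        # exact trapezoidal pressurization ratio is (w - dt/2)/w, not 1
        "ptp300": 100.0 * (1.0 - dt / (2 * 0.3)),
        "ptp500": 100.0 * (1.0 - dt / (2 * 0.5)),
        "baseline": baseline,
        "delta_p_set": plateau,
        "onset": 0.0,
    }
    return FixtureWaveform(samples=p, dt=dt, truth=truth)


def _exp_exhale(peak: float = -60.0, tau: float = 0.3,
                duration: float = 2.0, dt: float = 0.001) -> FixtureWaveform:
    """Exponential exhale-flow decay from `peak` (negative, l/min)."""
    t = np.arange(int(round(duration / dt))) * dt
    f = peak * np.exp(-t / tau)
    t10 = tau * math.log(10.0)
    i10 = math.ceil(t10 / dt - 1e-12)
    truth = {
        "peak": peak,
        "tau": tau,
        "t_10pct": t10,
        "i_10pct": i10,
        "flow_at_open": peak * math.exp(-i10 * dt / tau),
    }
    return FixtureWaveform(samples=f, dt=dt, truth=truth)


def _square_pressurization(target: float = 20.0, rise: float = 0.1,
                           duration: float = 1.0, dt: float = 0.001) -> FixtureWaveform:
    """Linear ramp 0 -> target over `rise`, then hold."""
    t = np.arange(int(round(duration / dt))) * dt
    p = np.minimum(t / rise, 1.0) * target
    truth = {"rise_time_95_ms": 0.95 * rise * 1e3, "target": target}
    return FixtureWaveform(samples=p, dt=dt, truth=truth)


_FIXTURES: dict[str, Callable[..., FixtureWaveform]] = {
    "triangle_dip": _triangle_dip,
    "exp_exhale": _exp_exhale,
    "square_pressurization": _square_pressurization,
}


def fixture_waveform(kind: str, **params) -> FixtureWaveform:
    """Build a registered analytic fixture with closed-form truth attached."""
    try:
        factory = _FIXTURES[kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {kind!r}; valid kinds: {', '.join(sorted(_FIXTURES))}"
        ) from None
    return factory(**params)
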