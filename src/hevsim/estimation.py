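"""Derived (ventilator-side) measurements.

Two independent tidal-volume estimators are provided: integration of the
proximal flow sensor, and an ideal-gas calculation from the pressure drop of
the buffer during delivery (adiabatic or isothermal).  The buffer's O2
fraction is likewise known by calculation, by running a mole balance over
the recorded fill and purge events, with a lagged-sensor model confirming
it.  Occlusion windows yield plateau pressure and intrinsic PEEP, from which
the static compliance follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .pneumatics import FO2_AIR, GAMMA, GasState, P_AMBIENT, R_GAS, T_AMBIENT

__all__ = [
    "FillEvent",
    "BreathRecord",
    "OcclusionResult",
    "O2Sensor",
    "buffer_delivered_volume",
    "calculated_fio2",
    "proximal_tidal_volume",
    "occlusion_measurements",
    "static_compliance",
]


@dataclass(frozen=True)
class FillEvent:
    """One buffer fill or purge segment.

    species: "air" or "o2".  Fills have pressure_after >= pressure_before;
    purges are recorded with species="air" and pressure_after <= before.
    Pressures absolute [Pa].
    """

    species: str
    pressure_before: float
    pressure_after: float
    temperature: float = T_AMBIENT
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.species not in ("air", "o2"):
            raise ValueError(f"species must be 'air' or 'o2', got {self.species!r}")
        if self.pressure_before <= 0 or self.pressure_after <= 0:
            raise ValueError("event pressures must be positive")
        if self.species == "o2" and self.pressure_after < self.pressure_before:
            raise ValueError("O2 events must be fills (pressure_after >= before)")


@dataclass(frozen=True)
class BreathRecord:
    """Per-breath outputs of the simulator."""

    breath_index: int
    t_start: float
    trigger_type: str            # "timed" | "patient"
    vt_proximal: float           # ml, proximal-flow integral
    vt_buffer: float             # ml, buffer pressure-drop calculation
    plateau_pressure: Optional[float] = None   # cmH2O, if a pause occurred
    intrinsic_peep: Optional[float] = None     # cmH2O, if a pre-inhale hold occurred
    fio2_calculated: float = FO2_AIR
    fio2_measured: float = FO2_AIR
    peak_flow: float = 0.0       # l/min
    peak_pressure: float = 0.0   # cmH2O


def buffer_delivered_volume(
    p1: float,
    t1: float,
    p2: float,
    v_buffer: float,
    gamma: float = GAMMA,
    ambient: GasState | None = None,
    thermal_mode: str = "adiabatic",
) -> float:
    """Volume delivered from the buffer, from its pressure drop p1 -> p2.

    During delivery the buffer inlet is closed, so the mole loss follows
    from the ideal-gas law.  Adiabatic mode uses the reversible adiabat
    T2 = t1*(p2/p1)^((gamma-1)/gamma); isothermal mode reduces to
    v_buffer*(p1-p2)/P_amb.  The result is referenced to ambient conditions
    and returned in ml.

    p1, p2 absolute [Pa]; t1 [K]; v_buffer [m3].
    """
    if p2 > p1:
        raise ValueError("p2 > p1: not a delivery interval")
    if thermal_mode not in ("adiabatic", "isothermal"):
        raise ValueError(f"unknown thermal_mode {thermal_mode!r}")
    p_amb = ambient.pressure_abs if ambient is not None else P_AMBIENT
    t_amb = ambient.temperature if ambient is not None else T_AMBIENT
    if thermal_mode == "isothermal":
        return v_buffer * (p1 - p2) / p_amb * 1e6
    t2 = t1 * (p2 / p1) ** ((gamma - 1.0) / gamma)
    dn = v_buffer / R_GAS * (p1 / t1 - p2 / t2)
    return dn * R_GAS * t_amb / p_amb * 1e6


def calculated_fio2(events: Iterable[FillEvent], initial: GasState) -> float:
    """Buffer O2 fraction from a running mole balance over fill/purge events.

    Each fill adds moles at the species purity (0.21 for air, 1.0 for O2);
    each purge removes gas at the then-current composition, which leaves the
    fraction unchanged.  Events must be time-ordered.
    """
    fo2 = initial.fo2
    p = initial.pressure_abs
    last_t = -math.inf
    for ev in events:
        if ev.timestamp < last_t:
            raise ValueError("events must be time-ordered")
        last_t = ev.timestamp
        dp = ev.pressure_after - ev.pressure_before
        if dp >= 0:
            purity = 1.0 if ev.species == "o2" else FO2_AIR
            fo2 = (fo2 * ev.pressure_before + purity * dp) / ev.pressure_after
        # outflow (purge/delivery) leaves the mole fraction unchanged
        p = ev.pressure_after
    return fo2


def proximal_tidal_volume(
    flow_trace: Sequence[float] | np.ndarray, dt: float
) -> float:
    """Inhaled volume [ml]: trapezoidal integral of the positive part of a
    uniformly sampled proximal flow trace [l/min] over the inhale phase."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    flow = np.asarray(flow_trace, dtype=float)
    if flow.ndim != 1:
        raise ValueError("flow_trace must be one-dimensional (uniform sampling)")
    if flow.size < 2:
        return 0.0
    pos = np.clip(flow, 0.0, None)
    return float(np.trapezoid(pos, dx=dt)) / 60.0 * 1000.0


@dataclass(frozen=True)
class OcclusionResult:
    pressure: float       # cmH2O, mean over the settled half of the window
    settled: bool         # False if peak-to-peak in that half > 0.5 cmH2O


def occlusion_measurements(
    pressure_trace: Sequence[float] | np.ndarray,
    dt: float,
    window: tuple[float, float],
    settle_tolerance: float = 0.5,
) -> OcclusionResult:
    """Plateau or intrinsic-PEEP readout from an occlusion window.

    `window` is the (start, end) of the occluded interval in seconds from
    the start of the trace; it must be at least 200 ms long and lie inside
    the trace.  The reading is the mean pressure over the final half of the
    window; a settling flag is cleared if the peak-to-peak variation in that
    half exceeds `settle_tolerance` cmH2O.
    """
    p = np.asarray(pressure_trace, dtype=float)
    t0, t1 = window
    if t1 - t0 < 0.2:
        raise ValueError("occlusion window must span at least 200 ms")
    i0 = int(round(t0 / dt))
    i1 = int(round(t1 / dt))
    if i0 < 0 or i1 > p.size:
        raise ValueError("occlusion window lies outside the trace")
    half = p[(i0 + i1) // 2 : i1]
    ptp = float(half.max() - half.min())
    return OcclusionResult(pressure=float(half.mean()), settled=ptp <= settle_tolerance)


def static_compliance(vt: float, plateau: float, total_peep: float) -> float:
    """Static compliance [ml/cmH2O] = VT / (plateau - total PEEP)."""
    if vt < 0:
        raise ValueError("vt must be >= 0")
    if vt == 0.0:
        return 0.0
    if plateau <= total_peep:
        raise ValueError(
            f"plateau ({plateau}) must exceed total PEEP ({total_peep}): "
            "compliance undefined"
        )
    return vt / (plateau - total_peep)


class O2Sensor:
    """First-order-lag O2 sensor with Gaussian read error.

    The zirconium-dioxide cell spying on the buffer is fast (response well
    under 4 s, modelled as tau = 1.5 s) and accurate to about 0.5% O2
    (one-sigma Gaussian error).
    """

    def __init__(self, tau: float = 1.5, sigma: float = 0.005,
                 initial: float = FO2_AIR, rng: np.random.Generator | None = None):
        self.tau = tau
        self.sigma = sigma
        self.value = initial
        self.rng = rng

    def step(self, true_fo2: float, dt: float) -> float:
        alpha = 1.0 - math.exp(-dt / self.tau) if self.tau > 0 else 1.0
        self.value += (true_fo2 - self.value) * alpha
        return self.value

    def read(self) -> float:
        if self.rng is None or self.sigma == 0.0:
            return self.value
        return self.value + self.rng.normal(0.0, self.sigma)
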