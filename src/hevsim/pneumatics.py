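"""Ideal-gas physics of the ventilator's pressure buffer and its valves.

The ventilator stores a breath's worth of gas in an intermediate buffer that
is filled from the air and O2 supplies to a target pressure and then emptied
into the patient through a proportional inhale valve.  Everything here is
ideal-gas bookkeeping: the buffer is a fixed rigid volume whose state is
(absolute pressure, temperature, O2 mole fraction); valves obey a linear
conductance law; species are tracked by mole balance so that the buffer's O2
fraction and the delivered volume can both be derived from pressure changes
alone.

Units: this module works in SI (Pa, m3, K, mol).  Helpers are provided to
convert from the clinical units used at the package surface (cmH2O, mbar,
l/min, ml).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "R_GAS",
    "GAMMA",
    "P_AMBIENT",
    "T_AMBIENT",
    "FO2_AIR",
    "CMH2O",
    "MBAR",
    "LPM",
    "GasState",
    "ValveSpec",
    "ValveState",
    "BufferDepletionError",
    "valve_flow",
    "buffer_step",
    "pressure_convert",
]

R_GAS = 8.314462618  # J/(mol K)
GAMMA = 1.4          # cp/cv, both species diatomic
P_AMBIENT = 101_300.0  # Pa (1013 mbar)
T_AMBIENT = 293.0      # K
FO2_AIR = 0.21

CMH2O = 98.0665  # Pa
MBAR = 100.0     # Pa
LPM = 1e-3 / 60.0  # m3/s per l/min


class BufferDepletionError(RuntimeError):
    """Buffer pressure fell to/below ambient while gas was being drawn.

    Signals a mis-sized buffer or scenario (the patient demanded more gas
    than the buffer holds); never silently clipped.
    """


@dataclass(frozen=True)
class GasState:
    """State of a rigid gas volume (the buffer, or an ambient reservoir).

    pressure_abs : absolute pressure [Pa]
    volume       : container volume [m3] (fixed)
    temperature  : [K]
    fo2          : O2 mole fraction in [0, 1]
    """

    pressure_abs: float
    volume: float
    temperature: float
    fo2: float = FO2_AIR

    def __post_init__(self) -> None:
        if not (self.pressure_abs > 0 and math.isfinite(self.pressure_abs)):
            raise ValueError(f"pressure_abs must be positive and finite, got {self.pressure_abs}")
        if not (self.volume > 0 and math.isfinite(self.volume)):
            raise ValueError(f"volume must be positive and finite, got {self.volume}")
        if not (self.temperature > 0 and math.isfinite(self.temperature)):
            raise ValueError(f"temperature must be positive and finite, got {self.temperature}")
        if not (0.0 <= self.fo2 <= 1.0):
            raise ValueError(f"fo2 must be in [0, 1], got {self.fo2}")

    @property
    def moles(self) -> float:
        """Total mole content n = pV/(RT)."""
        return self.pressure_abs * self.volume / (R_GAS * self.temperature)

    @property
    def o2_moles(self) -> float:
        return self.fo2 * self.moles


@dataclass(frozen=True)
class ValveSpec:
    """Linear-conductance valve.

    conductance     : volumetric flow per unit pressure difference at full
                      opening, referenced to outlet conditions [m3/s/Pa].
                      Use :func:`ValveSpec.from_clinical` for (l/min)/mbar.
    actuator_tau    : first-order opening lag [s]
    is_proportional : proportional valve (continuous opening) vs on/off
    check_valve     : blocks reverse flow (outlet pressure above inlet)
    """

    conductance: float
    actuator_tau: float = 0.005
    is_proportional: bool = False
    check_valve: bool = False

    def __post_init__(self) -> None:
        if self.conductance < 0:
            raise ValueError("conductance must be >= 0")
        if self.actuator_tau < 0:
            raise ValueError("actuator_tau must be >= 0")

    @classmethod
    def from_clinical(cls, conductance_lpm_per_mbar: float, **kw) -> "ValveSpec":
        """Build a spec from a conductance in (l/min)/mbar."""
        return cls(conductance=conductance_lpm_per_mbar * LPM / MBAR, **kw)


@dataclass
class ValveState:
    """Commanded and actual opening of a valve, both in [0, 1].

    The actual opening relaxes toward the commanded one with the spec's
    first-order actuator time constant.
    """

    commanded_opening: float = 0.0
    actual_opening: float = 0.0

    def command(self, opening: float, spec: ValveSpec) -> None:
        if not (0.0 <= opening <= 1.0):
            raise ValueError(f"commanded opening must be in [0,1], got {opening}")
        if not spec.is_proportional and opening not in (0.0, 1.0):
            raise ValueError("on/off valve only accepts commanded opening 0 or 1")
        self.commanded_opening = opening

    def step(self, spec: ValveSpec, dt: float) -> float:
        """Advance the actuator by dt and return the new actual opening."""
        if spec.actuator_tau == 0.0:
            self.actual_opening = self.commanded_opening
        else:
            alpha = 1.0 - math.exp(-dt / spec.actuator_tau)
            self.actual_opening += (self.commanded_opening - self.actual_opening) * alpha
        return self.actual_opening


def valve_flow(p_up: float, p_down: float, opening: float, spec: ValveSpec) -> float:
    """Volumetric flow [m3/s at outlet conditions] through a valve.

    Linear law Q = conductance * opening * (p_up - p_down); positive means
    up -> down.  A check valve returns 0 for adverse pressure gradients.
    """
    if not (0.0 <= opening <= 1.0):
        raise ValueError(f"opening must be in [0,1], got {opening}")
    if not (math.isfinite(p_up) and math.isfinite(p_down)) or p_up <= 0 or p_down <= 0:
        raise ValueError("pressures must be positive and finite")
    dp = p_up - p_down
    if dp <= 0.0 and spec.check_valve:
        return 0.0
    return spec.conductance * opening * dp


def _buffer_step_raw(
    p: float,
    t: float,
    fo2: float,
    volume: float,
    ndot_air: float,
    ndot_o2: float,
    ndot_out: float,
    dt: float,
    adiabatic: bool,
    t_in: float = T_AMBIENT,
) -> tuple[float, float, float]:
    """One Euler step of the buffer mole/energy balance on plain floats.

    Air enters at fo2=0.21, O2 at fo2=1.0, gas leaves at the current fo2.
    In adiabatic mode the first-law balance d(nT) = gamma*(T_in*ndot_in -
    T*ndot_out)*dt is used, which reduces to the reversible adiabat for pure
    outflow.  Returns (p, T, fo2).
    """
    n = p * volume / (R_GAS * t)
    n_o2 = fo2 * n
    dn_in = (ndot_air + ndot_o2) * dt
    dn_out = ndot_out * dt
    n_new = n + dn_in - dn_out
    n_o2_new = n_o2 + (FO2_AIR * ndot_air + ndot_o2 - fo2 * ndot_out) * dt
    if n_new <= 0.0:
        raise BufferDepletionError("buffer mole content driven to zero")
    if adiabatic:
        nT = n * t + GAMMA * (t_in * (ndot_air + ndot_o2) - t * ndot_out) * dt
        t_new = nT / n_new
    else:
        t_new = t
    p_new = n_new * R_GAS * t_new / volume
    fo2_new = n_o2_new / n_new
    # guard numerical dust at the boundaries of pure-species filling
    if fo2_new < 0.0:
        fo2_new = 0.0
    elif fo2_new > 1.0:
        fo2_new = 1.0
    return p_new, t_new, fo2_new


def buffer_step(
    state: GasState,
    inflow_air: float,
    inflow_o2: float,
    outflow: float,
    dt: float,
    thermal_mode: str = "isothermal",
) -> GasState:
    """Advance the buffer by one timestep.

    Flows are molar rates [mol/s] (convert volumetric valve flows with the
    local p, T at the valve outlet); dt must be positive and at most 10 ms so
    the explicit species/energy balance stays well inside its stability
    region.  thermal_mode selects an isothermal update (temperature pinned,
    appropriate for slow refills with wall heat exchange) or an adiabatic one
    (first-law energy balance, appropriate for fast delivery strokes).

    Raises BufferDepletionError if the pressure is driven to/below ambient
    while gas leaves the buffer.
    """
    if not (0.0 < dt <= 0.010):
        raise ValueError(f"dt must be in (0, 10 ms], got {dt}")
    if thermal_mode not in ("isothermal", "adiabatic"):
        raise ValueError(f"unknown thermal_mode {thermal_mode!r}")
    if inflow_air < 0 or inflow_o2 < 0 or outflow < 0:
        raise ValueError("flows must be non-negative")
    if inflow_air == 0.0 and inflow_o2 == 0.0 and outflow == 0.0:
        return state
    p, t, fo2 = _buffer_step_raw(
        state.pressure_abs,
        state.temperature,
        state.fo2,
        state.volume,
        inflow_air,
        inflow_o2,
        outflow,
        dt,
        adiabatic=(thermal_mode == "adiabatic"),
    )
    if outflow > 0.0 and p <= P_AMBIENT:
        raise BufferDepletionError(
            f"buffer pressure {p:.0f} Pa fell to/below ambient during outflow"
        )
    return replace(state, pressure_abs=p, temperature=t, fo2=fo2)


_UNIT_TO_PA = {"Pa": 1.0, "mbar": MBAR, "cmH2O": CMH2O}


def pressure_convert(
    value: float,
    from_unit: str,
    to_unit: str,
    *,
    from_gauge: bool = True,
    to_gauge: bool = True,
    ambient: float = P_AMBIENT,
) -> float:
    """Convert a pressure between Pa, mbar and cmH2O, gauge or absolute.

    1 cmH2O = 98.0665 Pa and 1 mbar = 100 Pa exactly; gauge <-> absolute uses
    the supplied ambient pressure [Pa].
    """
    try:
        f = _UNIT_TO_PA[from_unit]
        t = _UNIT_TO_PA[to_unit]
    except KeyError as e:
        raise ValueError(f"unknown pressure unit {e.args[0]!r}; use Pa, mbar or cmH2O") from None
    pa = value * f
    if from_gauge and not to_gauge:
        pa += ambient
    elif not from_gauge and to_gauge:
        pa -= ambient
    return pa / t
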