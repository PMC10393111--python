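"""Hydraulic plant: occluder statics, actuator dynamics, reservoir balance, sensors.

The controlled system is a tube occluder throttling flow out of a venous
reservoir.  A static exponential tube-crush map converts the *effective*
occluder opening (0-100 %) into flow; the actuator itself responds to
commands as a first-order lag with dead time; the reservoir integrates the
in/out flow imbalance.  Sensor emulation adds seeded Gaussian noise, a
first-order low-pass on flow signals and optional quantization on the level
signal (stand-in for a camera-based level readout).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PlantParams",
    "PlantState",
    "SensorConfig",
    "FlowSensorState",
    "OverflowModelError",
    "InfeasibleSetpointError",
    "GLYCERIN_LIKE",
    "BLOOD_LIKE",
    "PLANT_PRESETS",
    "occluder_static_flow",
    "occluder_static_inverse",
    "make_plant_state",
    "actuator_step",
    "reservoir_step",
    "init_flow_sensor",
    "sense_flow",
    "sense_level",
]


class OverflowModelError(ValueError):
    """Static map evaluated outside its numerically representable range."""


class InfeasibleSetpointError(ValueError):
    """Requested flow at or above the supremum of the static map."""


@dataclass(frozen=True)
class PlantParams:
    """The seven constants of the occluder/flow model.

    ``resistance_R`` and ``occluder_resistance_dR0`` are hydraulic
    resistances in consistent arbitrary units; ``full_open_flow_Q0`` is the
    flow at 100 % opening in L/min; ``shape_A`` and ``shape_K`` describe the
    tube-crush geometry; ``dead_time_L`` (s) and ``time_constant_T`` (s) are
    the actuator FOPDT constants.
    """

    resistance_R: float
    occluder_resistance_dR0: float
    full_open_flow_Q0: float
    shape_A: float
    shape_K: float
    dead_time_L: float
    time_constant_T: float

    def __post_init__(self) -> None:
        positive = {
            "resistance_R": self.resistance_R,
            "occluder_resistance_dR0": self.occluder_resistance_dR0,
            "full_open_flow_Q0": self.full_open_flow_Q0,
            "shape_A": self.shape_A,
            "shape_K": self.shape_K,
            "time_constant_T": self.time_constant_T,
        }
        for name, value in positive.items():
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")
        if not (math.isfinite(self.dead_time_L) and self.dead_time_L >= 0):
            raise ValueError(f"dead_time_L must be finite and >= 0, got {self.dead_time_L!r}")


# Synthetic presets: the source study never publishes its fitted constants, so
# these are plausible stand-ins for a 3/8" adult circuit primed with glycerin
# solution or blood.  Q0 leaves headroom above a 4 L/min venous peak.
GLYCERIN_LIKE = PlantParams(
    resistance_R=1.0,
    occluder_resistance_dR0=0.15,
    full_open_flow_Q0=5.5,
    shape_A=0.01,
    shape_K=0.08,
    dead_time_L=0.3,
    time_constant_T=1.5,
)
BLOOD_LIKE = PlantParams(
    resistance_R=1.25,
    occluder_resistance_dR0=0.2,
    full_open_flow_Q0=5.2,
    shape_A=0.009,
    shape_K=0.075,
    dead_time_L=0.35,
    time_constant_T=1.8,
)
PLANT_PRESETS = {"glycerin-like": GLYCERIN_LIKE, "blood-like": BLOOD_LIKE}


@dataclass
class PlantState:
    """Actuator + reservoir state advanced at a fixed step."""

    effective_opening: float  # %, the opening the hydraulics actually see
    delay_buffer: deque  # commanded openings not yet past the dead time
    reservoir_volume: float  # L
    time: float = 0.0  # s
    empty_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.effective_opening <= 100.0:
            raise ValueError("effective_opening must lie in [0, 100]")
        if self.reservoir_volume < 0:
            raise ValueError("reservoir_volume must be >= 0")


@dataclass(frozen=True)
class SensorConfig:
    """Noise/filter settings for the emulated flowmeters and level camera."""

    flow_noise_sd: float = 0.05  # L/min, white, before low-pass
    lowpass_cutoff: float = 1.0  # Hz, first-order denoising filter
    level_noise_sd: float = 0.002  # L
    level_quantum: float = 0.005  # L; 0 disables quantization
    seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_noise_sd < 0 or self.level_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be > 0")
        if self.level_quantum < 0:
            raise ValueError("level_quantum must be >= 0")


def _crush_term(effective_opening: float, params: PlantParams) -> float:
    """E = exp(K*O') - 1, guarded against overflow."""
    x = params.shape_K * effective_opening
    if x > 700.0:  # exp overflow threshold for float64
        raise OverflowModelError(
            f"exp({x:.1f}) overflows in the static occluder map; "
            "check shape_K / opening range"
        )
    return math.expm1(x)


def occluder_static_flow(effective_opening: float, params: PlantParams) -> float:
    """Steady-state flow (L/min) through the occluder at a given opening (%).

    Q = (1 + dR0/R) * Q0 * R * A * E / (1 + R*A*E + dR0*A*E) with
    E = exp(K*O') - 1.  Q(0) = 0 and Q -> Q0 as the opening grows; Q0 itself
    is never attained.
    """
    if not 0.0 <= effective_opening <= 100.0:
        raise ValueError(f"opening must be in [0, 100] %, got {effective_opening!r}")
    e = _crush_term(effective_opening, params)
    r, dr0 = params.resistance_R, params.occluder_resistance_dR0
    num = (1.0 + dr0 / r) * params.full_open_flow_Q0 * r * params.shape_A * e
    den = 1.0 + (r + dr0) * params.shape_A * e
    q = num / den
    if not math.isfinite(q):
        raise OverflowModelError("non-finite flow from static occluder map")
    return q


def occluder_static_inverse(flow: float, params: PlantParams) -> float:
    """Opening (%) that produces ``flow`` at steady state (closed form).

    Solving the static map for E gives E = Q / (B * (Q0 - Q)) with
    B = (R + dR0) * A, hence O' = ln(E + 1) / K.  Raises
    :class:`InfeasibleSetpointError` for flow >= Q0 (the supremum).
    """
    if flow < 0:
        raise ValueError(f"flow must be >= 0, got {flow!r}")
    q0 = params.full_open_flow_Q0
    if flow >= q0:
        raise InfeasibleSetpointError(
            f"flow {flow:g} L/min is at or above the static-map supremum {q0:g}"
        )
    b = (params.resistance_R + params.occluder_resistance_dR0) * params.shape_A
    e = flow / (b * (q0 - flow))
    return math.log1p(e) / params.shape_K


def make_plant_state(
    params: PlantParams,
    dt: float,
    *,
    initial_opening: float = 0.0,
    initial_volume: float = 0.45,
) -> PlantState:
    """Build a state whose delay buffer covers the dead time at step ``dt``.

    The buffer is pre-filled with the initial opening so the plant starts at
    rest (no phantom command transient).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_delay = round(params.dead_time_L / dt)
    buf = deque([initial_opening] * n_delay, maxlen=n_delay if n_delay else 1)
    return PlantState(
        effective_opening=initial_opening,
        delay_buffer=buf,
        reservoir_volume=initial_volume,
    )


def actuator_step(
    state: PlantState, command: float, dt: float, params: PlantParams
) -> PlantState:
    """Advance the occluder mechanism one step of the FOPDT model.

    The command enters a FIFO covering ``dead_time_L`` seconds; the command
    that emerges drives a forward-Euler step of dO'/dt = (u - O') / T.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    command = min(max(command, 0.0), 100.0)
    buf = state.delay_buffer
    if len(buf) and buf.maxlen:
        delayed = buf[0]
        buf.append(command)  # maxlen evicts the popped sample
    else:
        delayed = command
    new_opening = state.effective_opening + dt / params.time_constant_T * (
        delayed - state.effective_opening
    )
    new_opening = min(max(new_opening, 0.0), 100.0)
    return replace(
        state,
        effective_opening=new_opening,
        delay_buffer=buf,
        time=state.time + dt,
    )


def reservoir_step(
    volume: float, q_in: float, q_out: float, disturbance_in: float, dt: float
) -> tuple[float, bool]:
    """One mass-balance step: volume + net_flow * dt / 60, floored at zero.

    Flows are L/min, dt is seconds.  Returns ``(new_volume, emptied)`` where
    ``emptied`` marks a floor activation — the air-entrainment hazard state —
    rather than raising, so ablation runs that drain the reservoir complete.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    for name, val in (("q_in", q_in), ("q_out", q_out), ("disturbance_in", disturbance_in)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    new_volume = volume + (q_in - q_out + disturbance_in) * dt / 60.0
    if new_volume < 0.0:
        return 0.0, True
    return new_volume, False


@dataclass
class FlowSensorState:
    """Low-pass filter memory + RNG for one flowmeter channel."""

    filtered: float
    rng: np.random.Generator
    initialized: bool = True


def init_flow_sensor(sensor: SensorConfig, initial_flow: float = 0.0) -> FlowSensorState:
    return FlowSensorState(
        filtered=initial_flow, rng=np.random.default_rng(sensor.seed)
    )


def sense_flow(
    true_flow: float, sensor: SensorConfig, state: FlowSensorState, dt: float = 0.01
) -> tuple[float, FlowSensorState]:
    """Noisy, low-pass-filtered flow reading.

    Gaussian noise (sd ``flow_noise_sd``) is added sample-wise, then a
    first-order filter with pole matched to ``lowpass_cutoff`` denoises the
    signal.  Deterministic for a given seed.
    """
    noisy = true_flow
    if sensor.flow_noise_sd > 0:
        noisy += sensor.flow_noise_sd * state.rng.standard_normal()
    a = math.exp(-2.0 * math.pi * sensor.lowpass_cutoff * dt)
    state.filtered = a * state.filtered + (1.0 - a) * noisy
    return state.filtered, state


def sense_level(
    true_volume: float,
    sensor: SensorConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Noisy, quantized reservoir-level reading (camera emulation).

    With ``rng`` omitted a fresh generator is seeded from the config, so
    repeated calls reproduce exactly; pass a persistent generator for
    streaming use.
    """
    if true_volume < 0:
        raise ValueError("true_volume must be >= 0")
    if rng is None:
        rng = np.random.default_rng(sensor.seed)
    level = true_volume
    if sensor.level_noise_sd > 0:
        level += sensor.level_noise_sd * rng.standard_normal()
    if sensor.level_quantum > 0:
        level = round(level / sensor.level_quantum) * sensor.level_quantum
    return level
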