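"""Nested controller: 2-DOF model-matching flow loop inside an I-PD level loop.

Inner loop (flow): the raw reference — measured venous flow plus the level
loop's correction — is shaped by a first-order reference model into q_m.  A
feedforward path inverts the static occluder map at q_m; a feedback PID acts
on the matching error q_m - q_measured.  Their sum, clamped to the occluder
travel, is the commanded opening.

Outer loop (level): an I-PD regulator.  The integral acts on the level error
while the proportional and (filtered) derivative terms act on the measured
level only, so target steps produce no kick.  Its output is an additive
correction to the flow reference: a level below target yields a negative
correction (less arterial outflow, letting the reservoir refill).

Both integrators freeze while their output is clamped (conditional-
integration anti-windup).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .plant import InfeasibleSetpointError, PlantParams, occluder_static_inverse

__all__ = [
    "PIDGains",
    "IPDGains",
    "ControllerConfig",
    "ControllerState",
    "ControlOutput",
    "default_controller_config",
    "shape_reference",
    "flow_control_step",
    "level_control_step",
    "nested_control_step",
]


@dataclass(frozen=True)
class PIDGains:
    """Parallel-form PID gains; output %, input L/min."""

    kp: float
    ki: float
    kd: float
    deriv_filter_tau: float = 0.05  # s, first-order filter on the raw derivative

    def __post_init__(self) -> None:
        for name in ("kp", "ki", "kd", "deriv_filter_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class IPDGains:
    """I-PD gains for the level loop; output L/min, input L."""

    ki: float
    kp: float
    kd: float
    deriv_filter_tau: float = 0.2

    def __post_init__(self) -> None:
        for name in ("ki", "kp", "kd", "deriv_filter_tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ControllerConfig:
    ref_model_tau: float = 1.0  # s, reference-model (matching) time constant
    pid_flow: PIDGains = field(default_factory=lambda: PIDGains(kp=25.0, ki=20.0, kd=2.0, deriv_filter_tau=0.1))
    ipd_level: IPDGains = field(default_factory=lambda: IPDGains(ki=6.0, kp=40.0, kd=40.0, deriv_filter_tau=0.3))
    flow_correction_limit: float = 1.5  # L/min, clamp on the level-loop output
    occ_min: float = 0.0
    occ_max: float = 100.0
    sample_time: float = 0.01  # s
    #: if True the FF path also inverts the actuator's first-order lag by
    #: leading the reference with T * dq_m/dt (dead time is not invertible)
    ff_invert_lag: bool = True

    def __post_init__(self) -> None:
        if self.ref_model_tau < 0:
            raise ValueError("ref_model_tau must be >= 0")
        if self.sample_time <= 0:
            raise ValueError("sample_time must be > 0")
        if self.flow_correction_limit <= 0:
            raise ValueError("flow_correction_limit must be > 0")
        if not 0 <= self.occ_min < self.occ_max <= 100:
            raise ValueError("need 0 <= occ_min < occ_max <= 100")


def default_controller_config() -> ControllerConfig:
    return ControllerConfig()


@dataclass
class ControllerState:
    """Integrator/filter memory of both loops."""

    q_m: float = 0.0  # reference-model output
    q_m_deriv: float = 0.0  # L/min/s, analytic derivative of the reference model
    flow_integral: float = 0.0  # %, inner-loop integral term
    flow_deriv: float = 0.0  # L/min/s, filtered derivative of the matching error
    prev_flow_error: float = 0.0
    level_integral: float = 0.0  # L/min, outer-loop integral term
    level_deriv: float = 0.0  # L/s, filtered derivative of the measured level
    prev_level: float = 0.0
    flow_saturated: bool = False
    level_saturated: bool = False
    ff_infeasible: bool = False

    @classmethod
    def at_equilibrium(
        cls,
        initial_flow: float,
        initial_level: float,
        cfg: ControllerConfig,
    ) -> "ControllerState":
        """Bumpless start: reference model pre-settled, level integrator
        pre-loaded so the initial correction is zero at the initial level."""
        return cls(
            q_m=initial_flow,
            prev_flow_error=0.0,
            level_integral=-cfg.ipd_level.kp * initial_level,
            prev_level=initial_level,
        )


class ControlOutput(NamedTuple):
    occ_command: float  # %
    q_m: float  # L/min, shaped reference actually tracked
    level_correction: float  # L/min


def shape_reference(raw_reference: float, cfg: ControllerConfig, state: ControllerState) -> float:
    """First-order reference model; tau = 0 degenerates to a pass-through."""
    if raw_reference < 0:
        raw_reference = 0.0
    tau = cfg.ref_model_tau
    if tau <= 0:
        state.q_m = raw_reference
        state.q_m_deriv = 0.0
    else:
        a = math.exp(-cfg.sample_time / tau)
        state.q_m = a * state.q_m + (1.0 - a) * raw_reference
        state.q_m_deriv = (raw_reference - state.q_m) / tau
    return state.q_m


def flow_control_step(
    q_m: float,
    q_measured: float,
    params: PlantParams,
    cfg: ControllerConfig,
    state: ControllerState,
) -> float:
    """One step of the 2-DOF flow controller; returns the opening command (%)."""
    dt = cfg.sample_time
    g = cfg.pid_flow

    ff_target = q_m
    if cfg.ff_invert_lag:
        # lead the statics inversion so the actuator lag cancels; only the
        # dead time remains between q_m and the achieved flow
        ff_target = q_m + params.time_constant_T * state.q_m_deriv
    try:
        ff = occluder_static_inverse(max(ff_target, 0.0), params)
        state.ff_infeasible = False
    except InfeasibleSetpointError:
        ff = cfg.occ_max
        state.ff_infeasible = True

    error = q_m - q_measured
    raw_deriv = (error - state.prev_flow_error) / dt
    if g.deriv_filter_tau > 0:
        af = math.exp(-dt / g.deriv_filter_tau)
        deriv = af * state.flow_deriv + (1.0 - af) * raw_deriv
    else:
        deriv = raw_deriv
    integral_candidate = state.flow_integral + g.ki * error * dt

    u = ff + g.kp * error + integral_candidate + g.kd * deriv
    u_clamped = min(max(u, cfg.occ_min), cfg.occ_max)
    saturated = u != u_clamped
    # conditional integration: hold the integral while pushing into the limit
    if not (saturated and (u - u_clamped) * error > 0):
        state.flow_integral = integral_candidate
    state.flow_deriv = deriv
    state.prev_flow_error = error
    state.flow_saturated = saturated
    return u_clamped


def level_control_step(
    target_level: float,
    measured_level: float,
    cfg: ControllerConfig,
    state: ControllerState,
) -> float:
    """One step of the I-PD level regulator; returns the flow correction (L/min).

    The reservoir drains through the controlled occluder, so the plant gain
    from correction to level is negative; accordingly the integral acts on
    (measured - target) and the P/D terms enter with positive sign on the
    measurement: a high level commands extra outflow, a rising level is
    damped, and a level below target yields a negative correction.
    """
    dt = cfg.sample_time
    g = cfg.ipd_level

    raw_deriv = (measured_level - state.prev_level) / dt
    if g.deriv_filter_tau > 0:
        af = math.exp(-dt / g.deriv_filter_tau)
        deriv = af * state.level_deriv + (1.0 - af) * raw_deriv
    else:
        deriv = raw_deriv
    integral_candidate = state.level_integral + g.ki * (measured_level - target_level) * dt

    u = integral_candidate + g.kp * measured_level + g.kd * deriv
    lim = cfg.flow_correction_limit
    u_clamped = min(max(u, -lim), lim)
    saturated = u != u_clamped
    if not (saturated and (u - u_clamped) * (measured_level - target_level) > 0):
        state.level_integral = integral_candidate
    state.level_deriv = deriv
    state.prev_level = measured_level
    state.level_saturated = saturated
    return u_clamped


def nested_control_step(
    q_venous_measured: float,
    target_level: float,
    measured_level: float,
    q_arterial_measured: float,
    params: PlantParams,
    cfg: ControllerConfig,
    state: ControllerState,
    *,
    level_control_enabled: bool = True,
) -> ControlOutput:
    """Full cascade step: level correction -> reference shaping -> flow loop.

    With ``level_control_enabled`` False (ablation) the correction is
    identically zero and the flow loop simply tracks the venous flow.
    """
    if level_control_enabled:
        correction = level_control_step(target_level, measured_level, cfg, state)
    else:
        correction = 0.0
    q_ref_raw = max(q_venous_measured + correction, 0.0)
    q_m = shape_reference(q_ref_raw, cfg, state)
    command = flow_control_step(q_m, q_arterial_measured, params, cfg, state)
    return ControlOutput(command, q_m, correction)
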