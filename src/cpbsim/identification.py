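"""Nonlinear least-squares fitting of the plant constants.

Static side: the five constants of the occluder map are fitted jointly to
steady-state (opening, flow) sweep pairs with positivity bounds and seeded
multi-start, because the map depends on its parameters mostly through
products (R*A, dR0*A) and single starts can stall in flat valleys.  A fit is
judged by predictive equivalence of the flow curve, not parameter-wise
equality.

Dynamic side: dead time and time constant are fitted to a recorded step
response of the actuator against the delayed first-order model, using the
whole trajectory rather than the classic two-point method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .plant import PlantParams, occluder_static_flow

__all__ = [
    "SweepDataset",
    "StepDataset",
    "StaticFitResult",
    "DynamicFitResult",
    "IdentifiabilityError",
    "generate_sweep",
    "generate_step_response",
    "fit_static_params",
    "fit_dynamic_params",
]


class IdentifiabilityError(ValueError):
    """Data carry no information about the parameters (e.g. constant flow)."""


@dataclass(frozen=True)
class SweepDataset:
    """Steady-state occluder sweep: paired opening (%) / flow (L/min) arrays."""

    opening: np.ndarray
    flow: np.ndarray

    def __post_init__(self) -> None:
        opening = np.asarray(self.opening, dtype=float)
        flow = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "opening", opening)
        object.__setattr__(self, "flow", flow)
        if opening.shape != flow.shape or opening.ndim != 1:
            raise ValueError("opening and flow must be 1-D arrays of equal length")
        if opening.size < 6:
            raise ValueError("need at least 6 sweep points")
        if opening.min() < 0 or opening.max() > 100:
            raise ValueError("openings must lie in [0, 100] %")


@dataclass(frozen=True)
class StepDataset:
    """Recorded step response of the actuator (time in s, response in %)."""

    time: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", y)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("time and response must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise ValueError("response must be finite")


@dataclass(frozen=True)
class StaticFitResult:
    params: PlantParams  # dynamic constants copied from the initial guess
    residual_norm: float
    converged: bool
    n_restarts_used: int


@dataclass(frozen=True)
class DynamicFitResult:
    dead_time_L: float
    time_constant_T: float
    residual_norm: float
    converged: bool


def generate_sweep(
    params: PlantParams, n_points: int, noise_sd: float, seed: int
) -> SweepDataset:
    """Synthetic sweep on a uniform [0, 100] grid with seeded Gaussian noise."""
    if n_points < 6:
        raise ValueError("n_points must be >= 6")
    rng = np.random.default_rng(seed)
    opening = np.linspace(0.0, 100.0, n_points)
    flow = np.array([occluder_static_flow(o, params) for o in opening])
    if noise_sd > 0:
        flow = flow + noise_sd * rng.standard_normal(n_points)
    return SweepDataset(opening=opening, flow=flow)


def generate_step_response(
    params: PlantParams,
    duration: float = 15.0,
    dt: float = 0.01,
    step_to: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> StepDataset:
    """Analytic FOPDT response to a 0 -> ``step_to`` opening command."""
    t = np.arange(0.0, duration, dt)
    y = np.where(
        t >= params.dead_time_L,
        step_to * (1.0 - np.exp(-(t - params.dead_time_L) / params.time_constant_T)),
        0.0,
    )
    if noise_sd > 0:
        y = y + noise_sd * np.random.default_rng(seed).standard_normal(t.size)
    return StepDataset(time=t, response=y)


def _static_model(theta: np.ndarray, opening: np.ndarray) -> np.ndarray:
    r, dr0, q0, a, k = theta
    e = np.expm1(np.minimum(k * opening, 700.0))
    return (1.0 + dr0 / r) * q0 * r * a * e / (1.0 + (r + dr0) * a * e)


def fit_static_params(
    data: SweepDataset,
    initial_guess: PlantParams,
    n_restarts: int = 5,
    seed: int = 0,
) -> StaticFitResult:
    """Fit (R, dR0, Q0, A, K) by bounded nonlinear least squares.

    ``n_restarts`` seeded multiplicative perturbations of the initial guess
    are tried and the best residual kept.  Non-convergence is flagged, never
    silent.
    """
    if float(np.ptp(data.flow)) < 1e-12:
        raise IdentifiabilityError("sweep flow is constant; parameters unidentifiable")

    theta0 = np.array(
        [
            initial_guess.resistance_R,
            initial_guess.occluder_resistance_dR0,
            initial_guess.full_open_flow_Q0,
            initial_guess.shape_A,
            initial_guess.shape_K,
        ]
    )
    lb = np.full(5, 1e-8)
    ub = np.full(5, np.inf)
    rng = np.random.default_rng(seed)

    best = None
    used = 0
    for trial in range(max(n_restarts, 1)):
        start = theta0 if trial == 0 else theta0 * rng.uniform(0.5, 1.5, size=5)
        try:
            sol = least_squares(
                lambda th: _static_model(th, data.opening) - data.flow,
                np.clip(start, lb, ub),
                bounds=(lb, ub),
                method="trf",
            )
        except Exception:
            continue
        used = trial + 1
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-16:
            break
    if best is None:
        raise RuntimeError("all least-squares restarts failed")

    r, dr0, q0, a, k = best.x
    fitted = PlantParams(
        resistance_R=float(r),
        occluder_resistance_dR0=float(dr0),
        full_open_flow_Q0=float(q0),
        shape_A=float(a),
        shape_K=float(k),
        dead_time_L=initial_guess.dead_time_L,
        time_constant_T=initial_guess.time_constant_T,
    )
    return StaticFitResult(
        params=fitted,
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
        n_restarts_used=used,
    )


def fit_dynamic_params(data: StepDataset) -> DynamicFitResult:
    """Fit (dead time, time constant) of a delayed first-order step response.

    The step amplitude is a free nuisance parameter so a trace that has not
    fully settled does not bias (L, T).
    """
    y = data.response
    t = data.time
    y0 = float(y[0])
    amp0 = float(np.median(y[-max(len(y) // 20, 5):])) - y0
    if abs(amp0) < 1e-9:
        return DynamicFitResult(0.0, 0.0, float(np.linalg.norm(y - y0)), False)

    def model(p: np.ndarray) -> np.ndarray:
        ell, tau, amp = p
        resp = np.where(
            t >= ell,
            y0 + amp * (1.0 - np.exp(-(t - ell) / max(tau, 1e-9))),
            y0,
        )
        return resp - y

    # crude start: dead time where 5 % of the rise is reached, tau from 63.2 %
    frac = (y - y0) / amp0
    i5 = int(np.argmax(frac >= 0.05))
    i63 = int(np.argmax(frac >= 0.632))
    l0 = max(t[i5] - 0.05 * (t[i63] - t[i5]), 0.0)
    t0 = max(t[i63] - l0, 1e-3)
    sol = least_squares(
        model,
        np.array([l0, t0, amp0]),
        bounds=([0.0, 1e-9, -np.inf], [t[-1], np.inf, np.inf]),
        method="trf",
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
    )
    rms = float(np.linalg.norm(sol.fun) / np.sqrt(len(y)))
    converged = bool(sol.success) and rms < 0.2 * abs(float(sol.x[2]))
    return DynamicFitResult(
        dead_time_L=float(sol.x[0]),
        time_constant_T=float(sol.x[1]),
        residual_norm=float(np.linalg.norm(sol.fun)),
        converged=converged,
    )
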