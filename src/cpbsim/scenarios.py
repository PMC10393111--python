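"""Closed-loop trial runner and the two experiment protocols.

``run_trial`` advances plant, sensors and nested controller at a fixed step
and computes the J_Q%/J_L% metrics on the logged record.  The two preset
builders reproduce the study protocols: a 400 s perfusion run whose venous
flow ramps up, holds and ramps back down, and a 200 s disturbance run with
constant venous flow and two venting/suction episodes that add inflow to
the reservoir.  Sensor noise streams are derived from the trial seed, so a
(config, seed) pair fully determines every logged sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .control import (
    ControllerConfig,
    ControllerState,
    nested_control_step,
)
from .metrics_io import (
    TIMESERIES_COLUMNS,
    j_l_percent,
    j_q_excluded_count,
    j_q_percent,
)
from .plant import (
    PlantParams,
    SensorConfig,
    make_plant_state,
    actuator_step,
    occluder_static_flow,
    occluder_static_inverse,
    reservoir_step,
)

__all__ = [
    "ScenarioConfig",
    "TrialResult",
    "BatchSummary",
    "run_trial",
    "run_batch",
    "perfusion_scenario",
    "disturbance_scenario",
    "SCENARIO_PRESETS",
]


@dataclass(frozen=True)
class ScenarioConfig:
    duration: float  # s_t, s
    dt: float = 0.01  # s
    target_level: float = 0.45  # L_T, L
    #: piecewise-linear (time s, flow L/min) knots of the venous return
    venous_profile: tuple = ((0.0, 4.0),)
    #: (start s, stop s, magnitude L/min) suction episodes -> reservoir inflow
    disturbance_profile: tuple = ()
    sensor: SensorConfig = field(default_factory=SensorConfig)
    level_control_enabled: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.target_level <= 0:
            raise ValueError("target_level must be > 0")
        knots = tuple((float(t), float(q)) for t, q in self.venous_profile)
        if any(t1 >= t2 for (t1, _), (t2, _) in zip(knots, knots[1:])):
            raise ValueError("venous_profile knots must be time-sorted")
        if any(q < 0 for _, q in knots):
            raise ValueError("venous flows must be >= 0")
        episodes = tuple(
            (float(a), float(b), float(m)) for a, b, m in self.disturbance_profile
        )
        for a, b, _ in episodes:
            if not (0.0 <= a < b <= self.duration):
                raise ValueError(
                    f"disturbance episode ({a}, {b}) must satisfy 0 <= start < stop <= duration"
                )
        object.__setattr__(self, "venous_profile", knots)
        object.__setattr__(self, "disturbance_profile", episodes)

    @property
    def n_samples(self) -> int:
        return round(self.duration / self.dt)

    def venous_flow(self, t: float) -> float:
        knots = self.venous_profile
        times = [k[0] for k in knots]
        flows = [k[1] for k in knots]
        return float(np.interp(t, times, flows))

    def disturbance(self, t: float) -> float:
        return sum(m for a, b, m in self.disturbance_profile if a <= t < b)


@dataclass(frozen=True)
class TrialResult:
    table: pd.DataFrame  # trajectory in the fixed CSV column order
    j_q_percent: float
    j_l_percent: float
    n_samples: int
    n_excluded_q: int
    empty_reservoir_flag: bool
    seed: int


@dataclass(frozen=True)
class BatchSummary:
    """Quantile summary of per-trial metrics (boxplot convention)."""

    j_q_quantiles: dict  # min / q2.5 / median / q97.5 / max
    j_l_quantiles: dict


def _quantiles(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {
        "min": float(arr.min()),
        "q2.5": float(np.percentile(arr, 2.5)),
        "median": float(np.median(arr)),
        "q97.5": float(np.percentile(arr, 97.5)),
        "max": float(arr.max()),
    }


def run_trial(
    scenario: ScenarioConfig,
    plant: PlantParams,
    controller: ControllerConfig,
) -> TrialResult:
    """Simulate one closed-loop trial and evaluate both metrics.

    The loop starts at hydraulic equilibrium: occluder at the opening that
    matches the initial venous flow, reservoir at the target level, and the
    controller state initialized bumplessly.  An emptied reservoir is
    flagged, not raised, so ablation runs complete.
    """
    dt = scenario.dt
    n = scenario.n_samples
    cfg = replace(controller, sample_time=dt) if controller.sample_time != dt else controller
    sensor = scenario.sensor

    # independent, seed-derived noise streams (venous, arterial, level)
    ss = np.random.SeedSequence([int(scenario.seed), int(sensor.seed)])
    rng_v, rng_a, rng_l = (np.random.default_rng(s) for s in ss.spawn(3))
    noise_v = sensor.flow_noise_sd * rng_v.standard_normal(n) if sensor.flow_noise_sd else np.zeros(n)
    noise_a = sensor.flow_noise_sd * rng_a.standard_normal(n) if sensor.flow_noise_sd else np.zeros(n)
    noise_l = sensor.level_noise_sd * rng_l.standard_normal(n) if sensor.level_noise_sd else np.zeros(n)
    a_lp = math.exp(-2.0 * math.pi * sensor.lowpass_cutoff * dt)
    quantum = sensor.level_quantum

    q_v0 = scenario.venous_flow(0.0)
    occ0 = occluder_static_inverse(min(q_v0, plant.full_open_flow_Q0 * 0.999), plant)
    state = make_plant_state(
        plant, dt, initial_opening=occ0, initial_volume=scenario.target_level
    )
    ctrl = ControllerState.at_equilibrium(q_v0, scenario.target_level, cfg)
    q_art_true = occluder_static_flow(occ0, plant)
    qv_filt = q_v0
    qa_filt = q_art_true
    volume = scenario.target_level
    emptied = False

    log = {c: np.empty(n) for c in TIMESERIES_COLUMNS}
    venous_flow = scenario.venous_flow
    disturbance = scenario.disturbance

    for i in range(n):
        t = i * dt
        q_ven_true = venous_flow(t)
        d = disturbance(t)

        qv_filt = a_lp * qv_filt + (1.0 - a_lp) * (q_ven_true + noise_v[i])
        qa_filt = a_lp * qa_filt + (1.0 - a_lp) * (q_art_true + noise_a[i])
        level_meas = volume + noise_l[i]
        if quantum > 0.0:
            level_meas = round(level_meas / quantum) * quantum

        out = nested_control_step(
            qv_filt,
            scenario.target_level,
            level_meas,
            qa_filt,
            plant,
            cfg,
            ctrl,
            level_control_enabled=scenario.level_control_enabled,
        )

        state = actuator_step(state, out.occ_command, dt, plant)
        q_art_true = occluder_static_flow(state.effective_opening, plant)
        volume, just_emptied = reservoir_step(volume, q_ven_true, q_art_true, d, dt)
        emptied = emptied or just_emptied

        log["time_s"][i] = t
        log["q_venous"][i] = q_ven_true
        log["q_ref"][i] = out.q_m
        log["q_arterial"][i] = qa_filt
        log["occ_cmd"][i] = out.occ_command
        log["occ_eff"][i] = state.effective_opening
        log["level_L"][i] = volume
        log["level_meas_L"][i] = level_meas
        log["disturbance"][i] = d

    jq = j_q_percent(log["q_ref"], log["q_arterial"])
    jl = j_l_percent(log["level_meas_L"], scenario.target_level)
    return TrialResult(
        table=pd.DataFrame(log, columns=TIMESERIES_COLUMNS),
        j_q_percent=jq,
        j_l_percent=jl,
        n_samples=n,
        n_excluded_q=j_q_excluded_count(log["q_ref"]),
        empty_reservoir_flag=emptied,
        seed=scenario.seed,
    )


def run_batch(
    scenario: ScenarioConfig,
    plant: PlantParams,
    controller: ControllerConfig,
    n_trials: int,
    base_seed: int = 1,
) -> tuple[list[TrialResult], BatchSummary]:
    """Run ``n_trials`` independently seeded trials (seeds base_seed..+n-1)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    results = [
        run_trial(replace(scenario, seed=base_seed + k), plant, controller)
        for k in range(n_trials)
    ]
    summary = BatchSummary(
        j_q_quantiles=_quantiles([r.j_q_percent for r in results]),
        j_l_quantiles=_quantiles([r.j_l_percent for r in results]),
    )
    return results, summary


_PERFUSION_PRESETS = {
    "default": dict(
        duration=400.0,
        venous_profile=((0.0, 0.5), (150.0, 4.0), (250.0, 4.0), (400.0, 0.5)),
    ),
    "noiseless": dict(
        duration=400.0,
        venous_profile=((0.0, 0.5), (150.0, 4.0), (250.0, 4.0), (400.0, 0.5)),
        sensor=SensorConfig(flow_noise_sd=0.0, level_noise_sd=0.0, level_quantum=0.0),
    ),
}

_DISTURBANCE_PRESETS = {
    "default": dict(
        duration=200.0,
        venous_profile=((0.0, 4.0),),
        disturbance_profile=((50.0, 70.0, 0.5), (150.0, 170.0, 0.5)),
    ),
    "noiseless": dict(
        duration=200.0,
        venous_profile=((0.0, 4.0),),
        disturbance_profile=((50.0, 70.0, 0.5), (150.0, 170.0, 0.5)),
        sensor=SensorConfig(flow_noise_sd=0.0, level_noise_sd=0.0, level_quantum=0.0),
    ),
}


def perfusion_scenario(preset_name: str = "default", **overrides) -> ScenarioConfig:
    """Flow-up/hold/flow-down protocol: 400 s, venous 0.5 -> 4.0 -> 0.5 L/min."""
    if preset_name not in _PERFUSION_PRESETS:
        raise ValueError(
            f"unknown perfusion preset {preset_name!r}; "
            f"available: {sorted(_PERFUSION_PRESETS)}"
        )
    kwargs = dict(_PERFUSION_PRESETS[preset_name])
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def disturbance_scenario(preset_name: str = "default", **overrides) -> ScenarioConfig:
    """Venting/suction protocol: 200 s, two +0.5 L/min episodes at 50 s and 150 s."""
    if preset_name not in _DISTURBANCE_PRESETS:
        raise ValueError(
            f"unknown disturbance preset {preset_name!r}; "
            f"available: {sorted(_DISTURBANCE_PRESETS)}"
        )
    kwargs = dict(_DISTURBANCE_PRESETS[preset_name])
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


SCENARIO_PRESETS = {
    "perfusion": perfusion_scenario,
    "disturbance": disturbance_scenario,
}
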