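"""Evaluation metrics, trajectory CSV I/O and config loading/validation.

The two trial metrics are mean absolute percentage errors: flow tracking
J_Q% = (1/N) * sum |(q_m - q)/q_m| * 100 and level regulation
J_L% = (1/N) * sum |(L_T - L)/L_T| * 100.  J_Q% excludes samples with
|q_m| below a small floor (the relative error is singular there) and
reports how many were dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .control import ControllerConfig, IPDGains, PIDGains
from .plant import PLANT_PRESETS, PlantParams, SensorConfig

__all__ = [
    "MetricReport",
    "UndefinedMetricError",
    "TIMESERIES_COLUMNS",
    "QM_FLOOR_LPM",
    "j_q_percent",
    "j_l_percent",
    "read_timeseries",
    "write_timeseries",
    "load_config",
    "save_params",
]

TIMESERIES_COLUMNS = [
    "time_s",
    "q_venous",
    "q_ref",
    "q_arterial",
    "occ_cmd",
    "occ_eff",
    "level_L",
    "level_meas_L",
    "disturbance",
]

#: samples with |q_m| below this (L/min) are excluded from J_Q%
QM_FLOOR_LPM = 0.1


class UndefinedMetricError(ValueError):
    """Every sample was excluded; the metric has no value."""


@dataclass(frozen=True)
class MetricReport:
    j_q_percent: float
    j_l_percent: float
    n_samples: int
    target_level: float
    n_excluded_q: int = 0


def j_q_percent(
    q_m_series: np.ndarray, q_series: np.ndarray, floor: float = QM_FLOOR_LPM
) -> float:
    """Mean absolute flow-tracking error, %, over samples with |q_m| >= floor."""
    q_m = np.asarray(q_m_series, dtype=float)
    q = np.asarray(q_series, dtype=float)
    if q_m.shape != q.shape or q_m.size < 1:
        raise ValueError("series must be non-empty and of equal length")
    included = np.abs(q_m) >= floor
    if not included.any():
        raise UndefinedMetricError(
            f"all {q_m.size} samples fall below the |q_m| floor of {floor} L/min"
        )
    rel = np.abs((q_m[included] - q[included]) / q_m[included])
    return float(rel.mean() * 100.0)


def j_q_excluded_count(q_m_series: np.ndarray, floor: float = QM_FLOOR_LPM) -> int:
    q_m = np.asarray(q_m_series, dtype=float)
    return int(np.count_nonzero(np.abs(q_m) < floor))


def j_l_percent(level_series: np.ndarray, target_level: float) -> float:
    """Mean absolute level-regulation error, % of the target level."""
    if target_level <= 0:
        raise ValueError(f"target_level must be > 0, got {target_level!r}")
    level = np.asarray(level_series, dtype=float)
    if level.size < 1:
        raise ValueError("level series must be non-empty")
    return float(np.abs((target_level - level) / target_level).mean() * 100.0)


def write_timeseries(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory table as CSV in the fixed column order."""
    missing = [c for c in TIMESERIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    table[TIMESERIES_COLUMNS].to_csv(path, index=False, float_format="%.6g")


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read and validate a trajectory CSV written by :func:`write_timeseries`."""
    table = pd.read_csv(path)
    missing = [c for c in TIMESERIES_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    t = table["time_s"].to_numpy()
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    return table[TIMESERIES_COLUMNS]


# --- config loading ---------------------------------------------------------

_PLANT_KEYS = {"preset", "R", "dR0", "Q0", "A", "K", "dead_time", "tau"}
_SENSOR_KEYS = {
    "flow_noise_sd",
    "lowpass_cutoff",
    "level_noise_sd",
    "level_quantum",
    "seed",
}
_CONTROL_KEYS = {
    "ref_model_tau",
    "flow_kp",
    "flow_ki",
    "flow_kd",
    "flow_deriv_filter_tau",
    "level_ki",
    "level_kp",
    "level_kd",
    "level_deriv_filter_tau",
    "flow_correction_limit",
    "occ_min",
    "occ_max",
    "sample_time",
}


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = sorted(set(given) - allowed)
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}' section: {unknown}; allowed: {sorted(allowed)}"
        )


def _plant_from_dict(d: dict) -> PlantParams:
    _check_keys("plant", d, _PLANT_KEYS)
    if "preset" in d:
        preset = d["preset"]
        if preset not in PLANT_PRESETS:
            raise ValueError(
                f"unknown plant preset {preset!r}; available: {sorted(PLANT_PRESETS)}"
            )
        base = PLANT_PRESETS[preset]
        merged = {
            "R": base.resistance_R,
            "dR0": base.occluder_resistance_dR0,
            "Q0": base.full_open_flow_Q0,
            "A": base.shape_A,
            "K": base.shape_K,
            "dead_time": base.dead_time_L,
            "tau": base.time_constant_T,
        }
        merged.update({k: v for k, v in d.items() if k != "preset"})
        d = merged
    try:
        return PlantParams(
            resistance_R=float(d["R"]),
            occluder_resistance_dR0=float(d["dR0"]),
            full_open_flow_Q0=float(d["Q0"]),
            shape_A=float(d["A"]),
            shape_K=float(d["K"]),
            dead_time_L=float(d["dead_time"]),
            time_constant_T=float(d["tau"]),
        )
    except KeyError as exc:
        raise ValueError(f"plant section is missing key {exc.args[0]!r}") from None
    except ValueError as exc:
        raise ValueError(f"invalid plant parameter: {exc}") from None


def _sensor_from_dict(d: dict) -> SensorConfig:
    _check_keys("sensor", d, _SENSOR_KEYS)
    try:
        return SensorConfig(**d)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid sensor config: {exc}") from None


def _control_from_dict(d: dict) -> ControllerConfig:
    _check_keys("control", d, _CONTROL_KEYS)
    base = ControllerConfig()
    try:
        pid = PIDGains(
            kp=float(d.get("flow_kp", base.pid_flow.kp)),
            ki=float(d.get("flow_ki", base.pid_flow.ki)),
            kd=float(d.get("flow_kd", base.pid_flow.kd)),
            deriv_filter_tau=float(
                d.get("flow_deriv_filter_tau", base.pid_flow.deriv_filter_tau)
            ),
        )
        ipd = IPDGains(
            ki=float(d.get("level_ki", base.ipd_level.ki)),
            kp=float(d.get("level_kp", base.ipd_level.kp)),
            kd=float(d.get("level_kd", base.ipd_level.kd)),
            deriv_filter_tau=float(
                d.get("level_deriv_filter_tau", base.ipd_level.deriv_filter_tau)
            ),
        )
        return ControllerConfig(
            ref_model_tau=float(d.get("ref_model_tau", base.ref_model_tau)),
            pid_flow=pid,
            ipd_level=ipd,
            flow_correction_limit=float(
                d.get("flow_correction_limit", base.flow_correction_limit)
            ),
            occ_min=float(d.get("occ_min", base.occ_min)),
            occ_max=float(d.get("occ_max", base.occ_max)),
            sample_time=float(d.get("sample_time", base.sample_time)),
        )
    except ValueError as exc:
        raise ValueError(f"invalid control config: {exc}") from None


def load_config(path: str | Path) -> dict:
    """Load a YAML config with ``plant``/``sensor``/``control`` sections.

    Returns ``{"plant": PlantParams, "sensor": SensorConfig,
    "control": ControllerConfig}``; absent sections fall back to defaults,
    unknown sections or keys are rejected with a message naming them.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys("<top level>", raw, {"plant", "sensor", "control"})
    plant_d = raw.get("plant", {"preset": "glycerin-like"})
    return {
        "plant": _plant_from_dict(plant_d),
        "sensor": _sensor_from_dict(raw.get("sensor", {})),
        "control": _control_from_dict(raw.get("control", {})),
    }


def save_params(params: PlantParams, path: str | Path) -> None:
    """Write fitted plant constants as a loadable YAML config fragment."""
    doc = {
        "plant": {
            "R": float(params.resistance_R),
            "dR0": float(params.occluder_resistance_dR0),
            "Q0": float(params.full_open_flow_Q0),
            "A": float(params.shape_A),
            "K": float(params.shape_K),
            "dead_time": float(params.dead_time_L),
            "tau": float(params.time_constant_T),
        }
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
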