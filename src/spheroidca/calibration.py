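"""Growth-curve metrics and the one-at-a-time grid-search calibration.

The observable is the spheroid diameter, measured as the experimental
pipeline does: twice the mean of the 100 largest cell-centre distances from
the spheroid centre.  Agreement between a simulated and a reference growth
curve is scored with the coefficient of determination R², and parameters are
fitted by a grid search, one parameter at a time in a stated order, each
controlling a distinct feature of the curve (growth rate, plateau onset,
shrinkage slope, ...).  Parameter cross-correlations are deliberately not
explored.

Because the experimental growth curves are published separately, a
self-simulated reference generator is provided: it runs a scenario, samples
the diameter every other day (the experimental cadence) on the day-3-offset
clock and adds Gaussian measurement noise.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .growth import Trajectory, run_simulation
from .lattice import CellGrid

__all__ = [
    "GrowthCurve",
    "CalibrationParameter",
    "CalibrationSpec",
    "CalibrationResult",
    "spheroid_diameter",
    "r_squared",
    "simulate_scenario",
    "generate_reference_curve",
    "calibrate",
]

log = logging.getLogger("spheroidca")

#: number of extremal cell distances averaged into the diameter estimate
N_RIM_CELLS = 100


def spheroid_diameter(grid: CellGrid, n_rim: int = N_RIM_CELLS) -> float:
    """Spheroid diameter (µm): twice the mean of the ``n_rim`` largest radii.

    Radii are cell-centre distances to the centroid of the occupied voxels;
    if fewer than ``n_rim`` cells are present all of them are used.  Raises
    on an empty grid.
    """
    coords = np.argwhere(grid.occupied)
    if coords.size == 0:
        raise ValueError("cannot measure the diameter of an empty grid")
    c = coords.mean(axis=0)
    d = np.sqrt(((coords - c) ** 2).sum(axis=1)) * grid.config.voxel_edge_um
    k = min(n_rim, d.size)
    top = np.partition(d, d.size - k)[d.size - k :]
    return float(2.0 * top.mean())


@dataclass
class GrowthCurve:
    """Diameter time series on the experimental clock (days since seeding)."""

    times_days: np.ndarray
    diameters_um: np.ndarray
    sigma_um: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=np.float64)
        self.diameters_um = np.asarray(self.diameters_um, dtype=np.float64)
        if np.any(np.diff(self.times_days) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.diameters_um < 0):
            raise ValueError("diameters must be >= 0")

    @classmethod
    def from_trajectory(cls, traj: Trajectory, times_days: Sequence[float]) -> "GrowthCurve":
        """Linearly interpolate a trajectory at the requested days."""
        t = np.asarray(times_days, dtype=np.float64)
        d = np.interp(t, traj.times_days, traj.diameters_um)
        return cls(t, d)

    @classmethod
    def from_csv(cls, path) -> "GrowthCurve":
        df = pd.read_csv(path)
        return cls(df["day"].to_numpy(), df["diameter_um"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"day": self.times_days, "diameter_um": self.diameters_um}).to_csv(
            path, index=False
        )


def r_squared(sim: GrowthCurve, ref: GrowthCurve) -> float:
    """Coefficient of determination of ``sim`` against ``ref``.

    The simulated curve is linearly interpolated at the reference times;
    SS_tot is taken about the mean of the reference diameters.  A constant
    reference makes the objective undefined and raises.
    """
    y = ref.diameters_um
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("constant reference curve: R^2 is undefined")
    yhat = np.interp(ref.times_days, sim.times_days, sim.diameters_um)
    ss_res = float(((y - yhat) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class CalibrationParameter:
    """One fitted parameter: a dotted config path and its candidate grid."""

    name: str  # e.g. "growth.doubling_time_h"
    grid: Sequence[float]
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.grid) == 0:
            raise ValueError(f"empty grid for parameter {self.name}")


@dataclass
class CalibrationSpec:
    """Ordered one-at-a-time calibration plan."""

    parameters: List[CalibrationParameter]
    seed: int = 0  # fixed seed per evaluation keeps the objective deterministic


@dataclass
class CalibrationResult:
    """Fitted values, per-parameter objective traces and the final score."""

    params: Dict[str, float]
    traces: Dict[str, pd.DataFrame]
    best_r2: float
    warnings: List[str] = field(default_factory=list)

    def support_interval(self, name: str, delta_r2: float = 0.02) -> tuple:
        """Grid values whose R² lies within ``delta_r2`` of the optimum."""
        tr = self.traces[name].dropna()
        good = tr[tr["r2"] >= tr["r2"].max() - delta_r2]["value"]
        return float(good.min()), float(good.max())


def _set_dotted(cfg: ScenarioConfig, dotted: str, value) -> ScenarioConfig:
    data = cfg.model_dump()
    node = data
    parts = dotted.split(".")
    for p in parts[:-1]:
        node = node[p]
        if node is None:
            raise KeyError(f"cannot set {dotted}: missing block {p}")
    if parts[-1] not in node:
        raise KeyError(f"unknown parameter {dotted}")
    node[parts[-1]] = value
    return ScenarioConfig(**data)


def simulate_scenario(cfg: ScenarioConfig, seed: Optional[int] = None) -> Trajectory:
    """Seed a spheroid and run the configured scenario end to end."""
    rng = np.random.default_rng(cfg.run.seed if seed is None else seed)
    grid = cfg.build_grid(rng)
    return run_simulation(
        grid,
        cfg.schedule,
        cfg.growth,
        cfg.oxygen,
        cfg.treatment,
        rng,
        cfg.run.horizon_days,
        cfg.run.sample_every_h,
    )


def generate_reference_curve(
    cfg: ScenarioConfig, noise_sd_um: float, seed: int
) -> GrowthCurve:
    """Synthetic stand-in for an experimentally measured growth curve.

    Runs the scenario (with the scenario's own seed), samples the diameter
    every other day starting the day after growth begins, and adds
    independent Gaussian noise controlled by ``seed`` — so two seeds share
    the underlying trajectory and differ only in the noise draws.
    """
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be >= 0")
    traj = simulate_scenario(cfg)
    start = cfg.growth.acclimatization_offset_days
    days = np.arange(start + 1.0, cfg.run.horizon_days + 1e-9, 2.0)
    curve = GrowthCurve.from_trajectory(traj, days)
    noise_rng = np.random.default_rng(seed)
    noisy = curve.diameters_um + noise_rng.normal(0.0, noise_sd_um, size=days.size)
    return GrowthCurve(days, np.maximum(noisy, 0.0), sigma_um=np.full(days.size, noise_sd_um))


def calibrate(
    spec: CalibrationSpec, scenario: ScenarioConfig, ref: GrowthCurve
) -> CalibrationResult:
    """One-at-a-time grid search maximising R² against the reference curve.

    Parameters are visited in the given order; each grid is evaluated with
    all other parameters held at their current values and a fixed simulation
    seed, then the arg-max is locked in.  A failed simulation at a grid point
    is recorded as a warning and the point skipped.
    """
    cfg = scenario
    fitted: Dict[str, float] = {}
    traces: Dict[str, pd.DataFrame] = {}
    warns: List[str] = []
    best_r2 = float("nan")
    for par in spec.parameters:
        values, scores = [], []
        for v in par.grid:
            try:
                trial = _set_dotted(cfg, par.name, v)
                traj = simulate_scenario(trial, seed=spec.seed)
                sim = GrowthCurve(traj.times_days, traj.diameters_um)
                r2 = r_squared(sim, ref)
            except Exception as exc:  # noqa: BLE001 - record and move on
                msg = f"{par.name}={v}: {exc}"
                warns.append(msg)
                log.warning("calibration point failed: %s", msg)
                r2 = float("nan")
            values.append(v)
            scores.append(r2)
        tr = pd.DataFrame({"value": values, "r2": scores})
        traces[par.name] = tr
        if tr["r2"].notna().any():
            best_idx = tr["r2"].idxmax()
            best_val = tr.loc[best_idx, "value"]
            fitted[par.name] = best_val
            best_r2 = float(tr.loc[best_idx, "r2"])
            cfg = _set_dotted(cfg, par.name, best_val)
        else:
            warns.append(f"no valid grid point for {par.name}; parameter left unchanged")
    return CalibrationResult(params=fitted, traces=traces, best_r2=best_r2, warnings=warns)
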