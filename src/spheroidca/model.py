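"""Model / Results interface for fitting the automaton to growth-curve data.

:class:`SpheroidGrowthModel` wraps a reference growth curve, a simulation
scenario and a calibration plan the way a statistical model wraps data and a
design: ``fit()`` runs the one-at-a-time grid search and returns a
:class:`SpheroidFitResults` carrying the estimates, per-parameter objective
traces, grid-resolution support intervals and a ``summary()`` table;
``simulate()`` produces trajectories from the current (or fitted) parameters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationResult,
    CalibrationSpec,
    GrowthCurve,
    calibrate,
    r_squared,
    simulate_scenario,
)
from .config import ScenarioConfig
from .growth import Trajectory

__all__ = ["SpheroidGrowthModel", "SpheroidFitResults"]


class SpheroidGrowthModel:
    """A spheroid growth/response model bound to a reference curve."""

    def __init__(
        self,
        reference: GrowthCurve,
        scenario: Optional[ScenarioConfig] = None,
        calibration: Optional[CalibrationSpec] = None,
    ):
        self.reference = reference
        self.scenario = scenario or ScenarioConfig()
        self.calibration = calibration

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "day",
        diameter_col: str = "diameter_um",
        scenario: Optional[ScenarioConfig] = None,
        calibration: Optional[CalibrationSpec] = None,
    ) -> "SpheroidGrowthModel":
        ref = GrowthCurve(df[time_col].to_numpy(), df[diameter_col].to_numpy())
        return cls(ref, scenario=scenario, calibration=calibration)

    def simulate(self, seed: Optional[int] = None) -> Trajectory:
        """Run the bound scenario (after fit(), via the results object)."""
        return simulate_scenario(self.scenario, seed=seed)

    def fit(self) -> "SpheroidFitResults":
        if self.calibration is None:
            raise ValueError("no CalibrationSpec attached to this model")
        result = calibrate(self.calibration, self.scenario, self.reference)
        fitted_cfg = self.scenario
        from .calibration import _set_dotted

        for name, value in result.params.items():
            fitted_cfg = _set_dotted(fitted_cfg, name, value)
        return SpheroidFitResults(self, result, fitted_cfg)


@dataclass
class SpheroidFitResults:
    """Estimates and diagnostics from a grid-search calibration."""

    model: SpheroidGrowthModel
    result: CalibrationResult
    fitted_scenario: ScenarioConfig

    @property
    def params(self) -> Dict[str, float]:
        return self.result.params

    @property
    def rsquared(self) -> float:
        return self.result.best_r2

    def conf_int(self, delta_r2: float = 0.02) -> pd.DataFrame:
        """Grid-supported intervals: values within ``delta_r2`` of peak R²."""
        rows = []
        for name in self.params:
            lo, hi = self.result.support_interval(name, delta_r2)
            rows.append({"param": name, "lower": lo, "upper": hi})
        return pd.DataFrame(rows).set_index("param")

    def predict(self, times_days: Sequence[float], seed: Optional[int] = None) -> np.ndarray:
        """Simulated diameters (µm) at the requested days under the fit."""
        traj = simulate_scenario(self.fitted_scenario, seed=seed)
        return np.interp(np.asarray(times_days), traj.times_days, traj.diameters_um)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Spheroid growth model — one-at-a-time grid-search calibration",
            "=" * 62,
            f"{'parameter':<34}{'estimate':>10}{'support':>18}",
            "-" * 62,
        ]
        for name, value in self.params.items():
            lo, hi = ci.loc[name, "lower"], ci.loc[name, "upper"]
            lines.append(f"{name:<34}{value:>10.4g}{f'[{lo:.4g}, {hi:.4g}]':>18}")
        lines.append("-" * 62)
        lines.append(f"{'R^2 (final)':<34}{self.rsquared:>10.4f}")
        n = len(self.model.reference.times_days)
        lines.append(f"{'n reference points':<34}{n:>10d}")
        if self.result.warnings:
            lines.append(f"warnings: {len(self.result.warnings)} grid points failed")
        return "\n".join(lines)
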