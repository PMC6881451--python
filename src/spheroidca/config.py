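"""Scenario configuration: schema, defaults, loading and serialisation.

A scenario bundles the lattice geometry, growth / oxygen / treatment
parameter blocks, the treatment schedule and the run controls into one
validated object.  Configs are plain YAML; unknown keys are rejected and all
physical quantities carry explicit units in their key names.  Parameters that
default to values not taken from measured data (the illustrative LQ / AlphaR
coefficients in particular) are flagged in the run log when left at their
defaults.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .growth import GrowthParams, TreatmentEvent
from .lattice import CellGrid, LatticeConfig, seed_sphere
from .oxygen import OxygenParams
from .treatment import TreatmentParams

__all__ = ["RunConfig", "ScenarioConfig", "load_config", "save_config"]

log = logging.getLogger("spheroidca")

#: parameters whose defaults are illustrative rather than measured values
NON_PAPER_DEFAULTS = (
    ("treatment.rt.alpha_per_gy", 0.2),
    ("treatment.rt.beta_per_gy2", 0.02),
    ("treatment.rt.gamma_by_phase", (1.0, 1.0, 1.0, 1.0, 1.0)),
    ("treatment.ht.alpha0_per_cem43", 0.1),
    ("treatment.ht.beta_ht_per_cem43_2", 0.001),
    ("treatment.ht.t_delay_ht_to_death_sd_h", None),
    ("growth.jitter", 0.1),
    ("growth.phase_fractions", (0.40, 0.35, 0.20, 0.05)),
)


class RunConfig(BaseModel):
    """Run horizon, sampling, seeding and initial state."""

    model_config = ConfigDict(extra="forbid")

    horizon_days: float = 21.0
    sample_every_h: float = 24.0
    seed: int = 0
    initial_diameter_um: float = 200.0
    outdir: Optional[str] = None

    @field_validator("horizon_days", "sample_every_h", "initial_diameter_um")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v


class ScenarioConfig(BaseModel):
    """Fully resolved simulation scenario."""

    model_config = ConfigDict(extra="forbid")

    lattice: LatticeConfig = LatticeConfig(dims=(100, 100, 100))
    growth: GrowthParams = GrowthParams()
    oxygen: OxygenParams = OxygenParams()
    treatment: TreatmentParams = TreatmentParams()
    schedule: List[TreatmentEvent] = []
    run: RunConfig = RunConfig()

    def model_post_init(self, __context) -> None:
        for ev in self.schedule:
            if ev.kind == "RT" and self.treatment.rt is None:
                raise ValueError(
                    "schedule contains an RT event but treatment.rt (alpha, beta) is missing"
                )
            if ev.kind == "HT" and self.treatment.ht is None:
                raise ValueError(
                    "schedule contains an HT event but treatment.ht (alpha0, beta_HT) is missing"
                )
            if ev.kind == "RTHT" and (
                self.treatment.rt is None
                or self.treatment.ht is None
                or self.treatment.rtht is None
            ):
                raise ValueError(
                    "schedule contains an RTHT event but rt/ht/rtht parameter blocks are missing"
                )

    # ------------------------------------------------------------------ build
    def initial_cell_count(self) -> int:
        """Cells filling a dense sphere of the configured initial diameter."""
        r_vox = self.run.initial_diameter_um / 2.0 / self.lattice.voxel_edge_um
        return max(1, int(round(4.0 / 3.0 * np.pi * r_vox**3)))

    def build_grid(self, rng: np.random.Generator) -> CellGrid:
        grid = CellGrid(self.lattice)
        seed_sphere(
            grid,
            self.initial_cell_count(),
            rng,
            phase_durations_h=self.growth.phase_durations_h,
            jitter=self.growth.jitter,
        )
        return grid

    def log_non_paper_defaults(self) -> List[str]:
        """Names of parameters left at non-measured defaults (also logged)."""
        flagged = []
        for dotted, default in NON_PAPER_DEFAULTS:
            obj = self
            try:
                for part in dotted.split("."):
                    obj = getattr(obj, part)
            except AttributeError:
                continue
            if obj == default or (obj is None and default is None):
                flagged.append(dotted)
                log.info("non-paper default in effect: %s = %r", dotted, obj)
        return flagged


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML scenario; unknown keys raise naming the key."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    cfg = ScenarioConfig(**raw)
    cfg.log_non_paper_defaults()
    return cfg


def save_config(cfg: ScenarioConfig, path) -> None:
    """Serialise a resolved scenario back to YAML (round-trips losslessly)."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
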