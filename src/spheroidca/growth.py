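"""The cellular-automaton time-stepping loop for spheroid growth.

Each step of duration ``dt`` (1 h by default): the oxygen field is relaxed to
equilibrium and hypoxia flags updated; hypoxic cells turn necrotic with
probability ``p_hypoxiaDeath``; necrotic cells are cleared from the lattice
with probability ``p_clearNecrotic`` (together these two small probabilities
produce the growth plateau without extra minimum-time parameters); viable
cells advance their individual cycle timers, divide at M-exit into the
alternating Moore / von Neumann neighbourhoods (entering reversible
quiescence G0 when no site is free, re-entering as soon as space frees up),
and dying irradiated cells resolve mitotic catastrophe at their division
attempts; finally the cell mass is compacted inward.  Untreated normoxic
cells never die and divide without limit.

Simulated time is kept on the *experimental* clock: growth begins on day 3
after seeding, the allowance for cell attachment and acclimatisation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator

from . import _kernels
from .lattice import MOORE, VONNEUMANN, CellGrid, Fate, Phase, compact_inward, neighbourhood_offsets
from .oxygen import OxygenField, OxygenParams, flag_hypoxia, relax_to_equilibrium
from .treatment import (
    RTParams,
    TreatmentParams,
    apply_combination,
    apply_hyperthermia,
    apply_radiation,
)

__all__ = [
    "GrowthParams",
    "TreatmentEvent",
    "Trajectory",
    "step",
    "run_simulation",
]


class GrowthParams(BaseModel):
    """Untreated-growth parameters.

    Defaults are the fitted HCT116 values: 28 h doubling time,
    p_hypoxiaDeath = 0.01 and p_clearNecrotic = 0.001 per hourly step, with
    growth starting on experimental day 3.  ``phase_fractions`` split the
    doubling time over G1/S/G2/M; ``jitter`` is the half-width of the
    multiplicative Uniform(1-j, 1+j) spread of per-cell phase durations drawn
    at birth (desynchronises lineages).  With ``hypoxic_arrest`` set, hypoxic
    cells pause cycle progression until reoxygenated.
    """

    model_config = ConfigDict(extra="forbid")

    doubling_time_h: float = 28.0
    phase_fractions: Tuple[float, float, float, float] = (0.40, 0.35, 0.20, 0.05)
    p_hypoxia_death: float = 0.01
    p_clear_necrotic: float = 0.001
    dt_h: float = 1.0
    acclimatization_offset_days: float = 3.0
    jitter: float = 0.1
    hypoxic_arrest: bool = True

    @field_validator("p_hypoxia_death", "p_clear_necrotic")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("per-step probabilities must lie in [0, 1]")
        return v

    @field_validator("doubling_time_h", "dt_h")
    @classmethod
    def _pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("phase_fractions")
    @classmethod
    def _fracs(cls, v):
        if any(f <= 0 for f in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must be positive and sum to 1")
        return v

    @property
    def phase_durations_h(self) -> np.ndarray:
        return np.asarray(self.phase_fractions, dtype=np.float64) * self.doubling_time_h


class TreatmentEvent(BaseModel):
    """A scheduled exposure on the experimental clock."""

    model_config = ConfigDict(extra="forbid")

    time_days: float
    kind: str  # RT | HT | RTHT
    dose_gy: float = 0.0
    t43_cem43: float = 0.0

    @field_validator("kind")
    @classmethod
    def _kind(cls, v: str) -> str:
        if v not in ("RT", "HT", "RTHT"):
            raise ValueError("event kind must be RT, HT or RTHT")
        return v


@dataclass
class Trajectory:
    """Time series of spheroid diameter and compartment counts."""

    times_h: np.ndarray
    diameters_um: np.ndarray
    counts: Dict[str, np.ndarray]

    COMPARTMENTS = ("cycling", "quiescent", "dying_rt", "dying_ht", "necrotic")

    @property
    def times_days(self) -> np.ndarray:
        return self.times_h / 24.0

    @property
    def total_cells(self) -> np.ndarray:
        return sum(self.counts[c] for c in self.COMPARTMENTS)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times_h, "diameter_um": self.diameters_um})
        df["n_cycling"] = self.counts["cycling"]
        df["n_G0"] = self.counts["quiescent"]
        df["n_dyingRT"] = self.counts["dying_rt"]
        df["n_dyingHT"] = self.counts["dying_ht"]
        df["n_necrotic"] = self.counts["necrotic"]
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _compartment_counts(grid: CellGrid, gp: GrowthParams) -> Dict[str, int]:
    ph = grid.phase
    occ = ph != -1
    nec = ph == int(Phase.NECROTIC)
    dying_rt = occ & ~nec & (grid.fate == int(Fate.DYING_RT))
    dying_ht = occ & ~nec & (grid.fate == int(Fate.DYING_HT))
    rest = occ & ~nec & ~dying_rt & ~dying_ht
    quiescent = rest & ((ph == int(Phase.G0)) | (gp.hypoxic_arrest & grid.hypoxic))
    cycling = rest & ~quiescent
    return {
        "cycling": int(cycling.sum()),
        "quiescent": int(quiescent.sum()),
        "dying_rt": int(dying_rt.sum()),
        "dying_ht": int(dying_ht.sum()),
        "necrotic": int(nec.sum()),
    }


def step(
    grid: CellGrid,
    field: Optional[OxygenField],
    gp: GrowthParams,
    op: OxygenParams,
    rng: np.random.Generator,
    rt_params: Optional[RTParams] = None,
) -> Tuple[OxygenField, int, int]:
    """Advance the automaton by one time step ``gp.dt_h``.

    Returns the relaxed oxygen field (reusable as a warm start) and the
    numbers of divisions and removals, so callers can assert the per-step
    bookkeeping N(t+dt) = N(t) + divisions - removals.
    """
    field = relax_to_equilibrium(grid, op, field)
    flag_hypoxia(field, grid, op.hypoxia_threshold_mmhg)

    if grid.rt_time_h is None:
        p_mit = (rt_params or RTParams()).p_mitotic_death_late
    else:
        t_since_days = (grid.t_h - grid.rt_time_h) / 24.0
        p_mit = (rt_params or RTParams()).p_mitotic_death(t_since_days)

    coords = np.argwhere(grid.occupied)
    if coords.size:
        perm = rng.permutation(len(coords))
        coords = coords[perm]
        c = grid.centroid
        born = np.zeros(grid.dims, dtype=np.bool_)
        seed = int(rng.integers(2**31 - 1))
        n_div, n_rem = _kernels.step_cells(
            *grid.state_arrays(),
            born,
            np.ascontiguousarray(coords[:, 0]),
            np.ascontiguousarray(coords[:, 1]),
            np.ascontiguousarray(coords[:, 2]),
            c[0],
            c[1],
            c[2],
            gp.phase_durations_h,
            gp.dt_h,
            gp.p_hypoxia_death,
            gp.p_clear_necrotic,
            p_mit,
            gp.jitter,
            gp.hypoxic_arrest,
            neighbourhood_offsets(2, MOORE),
            neighbourhood_offsets(2, VONNEUMANN),
            seed,
        )
        compact_inward(grid, rng)
    else:
        n_div = n_rem = 0
    grid.t_h += gp.dt_h
    return field, n_div, n_rem


def run_simulation(
    initial: CellGrid,
    schedule: Sequence[TreatmentEvent],
    gp: GrowthParams,
    op: OxygenParams,
    tp: Optional[TreatmentParams],
    rng: np.random.Generator,
    horizon_days: float,
    sample_every_h: Optional[float] = None,
) -> Trajectory:
    """Run the automaton from day 3 to the horizon, applying scheduled events.

    The trajectory records diameter and compartment counts at the sampling
    cadence (every step by default).  Raises a configuration error for events
    scheduled outside the run window or lacking the required parameters.
    """
    from .calibration import spheroid_diameter  # local import avoids a cycle

    tp = tp or TreatmentParams()
    start_h = gp.acclimatization_offset_days * 24.0
    horizon_h = horizon_days * 24.0
    events = sorted(schedule, key=lambda e: e.time_days)
    for ev in events:
        t_h = ev.time_days * 24.0
        if t_h < start_h - 1e-9 or t_h > horizon_h + 1e-9:
            raise ValueError(
                f"event at day {ev.time_days} outside run window "
                f"[{start_h / 24}, {horizon_days}] days"
            )
        if ev.kind == "RT" and tp.rt is None:
            raise ValueError("RT event scheduled but no RT parameters (alpha, beta) given")
        if ev.kind == "HT" and tp.ht is None:
            raise ValueError("HT event scheduled but no HT parameters (alpha0, beta_HT) given")
        if ev.kind == "RTHT" and (tp.rt is None or tp.ht is None or tp.rtht is None):
            raise ValueError("RTHT event scheduled but combination parameters missing")

    grid = initial
    grid.t_h = start_h
    dt = gp.dt_h
    sample_every_h = sample_every_h or dt
    n_steps = int(round((horizon_h - start_h) / dt))

    times: List[float] = []
    diams: List[float] = []
    counts: Dict[str, List[int]] = {c: [] for c in Trajectory.COMPARTMENTS}

    field: Optional[OxygenField] = None

    def record() -> None:
        times.append(grid.t_h)
        diams.append(spheroid_diameter(grid) if grid.n_cells else 0.0)
        for name, v in _compartment_counts(grid, gp).items():
            counts[name].append(v)

    record()
    ev_idx = 0
    next_sample = start_h + sample_every_h
    for _ in range(n_steps):
        # events due at (or before) the current step boundary fire first
        while ev_idx < len(events) and events[ev_idx].time_days * 24.0 <= grid.t_h + 1e-9:
            ev = events[ev_idx]
            field = relax_to_equilibrium(grid, op, field)
            flag_hypoxia(field, grid, op.hypoxia_threshold_mmhg)
            if ev.kind == "RT":
                apply_radiation(grid, ev.dose_gy, tp.rt, field, rng)
            elif ev.kind == "HT":
                apply_hyperthermia(grid, ev.t43_cem43, tp.ht, rng)
            else:
                apply_combination(
                    grid, ev.dose_gy, ev.t43_cem43, tp.rt, tp.ht, tp.rtht, field, rng
                )
            ev_idx += 1
        n_before = grid.n_cells
        field, n_div, n_rem = step(grid, field, gp, op, rng, tp.rt)
        n_after = grid.n_cells
        if n_after != n_before + n_div - n_rem:
            raise AssertionError(
                f"bookkeeping violated at t={grid.t_h} h: "
                f"{n_before} + {n_div} - {n_rem} != {n_after}"
            )
        if grid.t_h + 1e-9 >= next_sample:
            record()
            next_sample += sample_every_h

    return Trajectory(
        times_h=np.asarray(times),
        diameters_um=np.asarray(diams),
        counts={k: np.asarray(v) for k, v in counts.items()},
    )
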