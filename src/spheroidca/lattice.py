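"""Fixed-lattice substrate for the spheroid cellular automaton.

Cells live on a 3D cubic lattice with one cell per voxel (voxel edge 12 µm by
default, the average HCT116 cell size).  This module provides the occupancy
container (:class:`CellGrid`), the Moore / von Neumann neighbourhood geometry
used during division, placement of an initial dense sphere, and the inward
compaction that keeps the cell mass a dense, approximately spherical aggregate.

Conventions
-----------
* Voxel coordinates are 0-based integer triples ``(i, j, k)``.
* The physical centre of voxel ``i`` along an axis is ``(i + 0.5) * voxel_edge``;
  distances between voxel centres therefore reduce to index-space distances
  scaled by the voxel edge.  All reported distances are in µm.
* The centroid of the cell mass is the mean index coordinate of occupied
  voxels (a continuous triple, recomputed on demand).
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from . import _kernels

__all__ = [
    "Phase",
    "Fate",
    "MOORE",
    "VONNEUMANN",
    "LatticeConfig",
    "Cell",
    "CellGrid",
    "neighbourhood_offsets",
    "neighbourhood_sites",
    "find_division_site",
    "compact_inward",
    "seed_sphere",
    "dense_sphere_grid",
]

EMPTY = np.int8(-1)


class Phase(IntEnum):
    """Cell-cycle phase codes as stored on the lattice."""

    G1 = 0
    S = 1
    G2 = 2
    M = 3
    G0 = 4
    NECROTIC = 5


class Fate(IntEnum):
    """Treatment-fate label of a cell."""

    VIABLE = 0
    DYING_RT = 1
    DYING_HT = 2


MOORE = "MOORE"
VONNEUMANN = "VONNEUMANN"

#: Default cycling-phase durations (h) for a 28 h doubling time split
#: G1/S/G2/M = 0.40/0.35/0.20/0.05.  Used when seeding cells without an
#: explicit growth parameterisation.
DEFAULT_PHASE_DURATIONS_H = (11.2, 9.8, 5.6, 1.4)


class LatticeConfig(BaseModel):
    """Geometry of the computational lattice.

    Parameters
    ----------
    dims
        Number of voxels along each axis (at least 3 per axis).
    voxel_edge_mm
        Cubic voxel edge length in mm.  The default 0.012 mm matches the
        average diameter of an HCT116 cell so that one voxel holds one cell.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dims: Tuple[int, int, int] = (200, 200, 200)
    voxel_edge_mm: float = 0.012

    @field_validator("dims")
    @classmethod
    def _dims_min(cls, v: Tuple[int, int, int]) -> Tuple[int, int, int]:
        if any(d < 3 for d in v):
            raise ValueError("lattice dims must be at least 3 voxels per axis")
        return v

    @field_validator("voxel_edge_mm")
    @classmethod
    def _edge_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("voxel_edge_mm must be > 0")
        return v

    @property
    def voxel_edge_um(self) -> float:
        return self.voxel_edge_mm * 1000.0


@dataclass
class Cell:
    """State of a single lattice agent.

    ``duration_scale`` is a per-cell multiplicative jitter applied to every
    cycling-phase duration; the actual durations are
    ``duration_scale * phase_fraction * doubling_time``.
    """

    phase: Phase = Phase.G1
    cycle_clock: float = 0.0
    duration_scale: float = 1.0
    fate: Fate = Fate.VIABLE
    death_delay: float = 0.0
    arrest_remaining: float = 0.0
    hypoxic: bool = False
    division_parity: int = 0

    def __post_init__(self) -> None:
        if self.cycle_clock < 0:
            raise ValueError("cycle_clock must be >= 0")
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be > 0")
        if self.death_delay < 0:
            raise ValueError("death_delay must be >= 0")


def _build_offsets(order: int, kind: str) -> np.ndarray:
    rng = range(-order, order + 1)
    out = []
    for dx in rng:
        for dy in rng:
            for dz in rng:
                if dx == dy == dz == 0:
                    continue
                if kind == MOORE:
                    if max(abs(dx), abs(dy), abs(dz)) <= order:
                        out.append((dx, dy, dz))
                elif kind == VONNEUMANN:
                    if abs(dx) + abs(dy) + abs(dz) <= order:
                        out.append((dx, dy, dz))
                else:
                    raise ValueError(f"unknown neighbourhood kind: {kind!r}")
    return np.array(out, dtype=np.int64)


# Precomputed offset tables used by both the Python API and the numba kernels.
OFFSETS = {
    (1, MOORE): _build_offsets(1, MOORE),
    (2, MOORE): _build_offsets(2, MOORE),
    (1, VONNEUMANN): _build_offsets(1, VONNEUMANN),
    (2, VONNEUMANN): _build_offsets(2, VONNEUMANN),
}


def neighbourhood_offsets(order: int, kind: str) -> np.ndarray:
    """Return the (n, 3) integer offsets of a neighbourhood, excluding origin."""
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if kind not in (MOORE, VONNEUMANN):
        raise ValueError(f"kind must be {MOORE!r} or {VONNEUMANN!r}")
    return OFFSETS[(order, kind)]


def neighbourhood_sites(
    x: Sequence[int], order: int, kind: str, dims: Sequence[int]
) -> list[tuple[int, int, int]]:
    """In-bounds neighbourhood coordinates of voxel ``x``, excluding ``x``.

    Moore neighbourhoods use the Chebyshev metric (``|.|_inf <= order``),
    von Neumann neighbourhoods the Manhattan metric (``|.|_1 <= order``).
    """
    x = tuple(int(c) for c in x)
    if len(x) != 3 or any(c < 0 or c >= d for c, d in zip(x, dims)):
        raise ValueError(f"coordinate {x} outside lattice of dims {tuple(dims)}")
    offs = neighbourhood_offsets(order, kind)
    pts = offs + np.asarray(x, dtype=np.int64)
    ok = np.all((pts >= 0) & (pts < np.asarray(dims, dtype=np.int64)), axis=1)
    return [tuple(int(v) for v in p) for p in pts[ok]]


class CellGrid:
    """3D occupancy lattice mapping voxels to cells.

    The grid stores cell state as a structure of per-voxel arrays (phase,
    cycle clock, fate, timers, ...) rather than as Python objects, so the
    time-stepping kernels can run over them directly.  :meth:`get_cell` /
    :meth:`set_cell` provide an object view for inspection and tests.
    """

    def __init__(self, config: LatticeConfig):
        self.config = config
        shape = tuple(config.dims)
        self.phase = np.full(shape, EMPTY, dtype=np.int8)
        self.clock = np.zeros(shape, dtype=np.float64)
        self.scale = np.ones(shape, dtype=np.float64)
        self.fate = np.zeros(shape, dtype=np.int8)
        self.delay = np.zeros(shape, dtype=np.float64)
        self.arrest = np.zeros(shape, dtype=np.float64)
        self.hypoxic = np.zeros(shape, dtype=np.bool_)
        self.parity = np.zeros(shape, dtype=np.int8)
        #: simulation clock in experimental hours since seeding
        self.t_h: float = 0.0
        #: time of the most recent radiation exposure (experimental hours),
        #: None if never irradiated
        self.rt_time_h: Optional[float] = None

    # ------------------------------------------------------------------ masks
    @property
    def dims(self) -> Tuple[int, int, int]:
        return tuple(self.config.dims)

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of voxels holding a cell (any state, incl. necrotic)."""
        return self.phase != EMPTY

    @property
    def consuming(self) -> np.ndarray:
        """Mask of metabolically active cells (everything but necrotic)."""
        return (self.phase != EMPTY) & (self.phase != int(Phase.NECROTIC))

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.phase != EMPTY))

    @property
    def centroid(self) -> Optional[np.ndarray]:
        """Mean index coordinate of occupied voxels, or None if empty."""
        coords = np.argwhere(self.phase != EMPTY)
        if coords.size == 0:
            return None
        return coords.mean(axis=0)

    @property
    def centroid_um(self) -> Optional[np.ndarray]:
        c = self.centroid
        if c is None:
            return None
        return (c + 0.5) * self.config.voxel_edge_um

    def bounding_box(self, margin: int = 0) -> Tuple[int, int, int, int, int, int]:
        """Inclusive-exclusive bounds of the occupied region, clipped to lattice."""
        occ = self.phase != EMPTY
        if not occ.any():
            return (0, 0, 0, 0, 0, 0)
        idx = np.argwhere(occ)
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + margin, np.asarray(self.dims))
        return (int(lo[0]), int(hi[0]), int(lo[1]), int(hi[1]), int(lo[2]), int(hi[2]))

    # ------------------------------------------------------------- cell views
    def get_cell(self, x: Sequence[int]) -> Optional[Cell]:
        i, j, k = (int(c) for c in x)
        if self.phase[i, j, k] == EMPTY:
            return None
        return Cell(
            phase=Phase(int(self.phase[i, j, k])),
            cycle_clock=float(self.clock[i, j, k]),
            duration_scale=float(self.scale[i, j, k]),
            fate=Fate(int(self.fate[i, j, k])),
            death_delay=float(self.delay[i, j, k]),
            arrest_remaining=float(self.arrest[i, j, k]),
            hypoxic=bool(self.hypoxic[i, j, k]),
            division_parity=int(self.parity[i, j, k]),
        )

    def set_cell(self, x: Sequence[int], cell: Cell) -> None:
        i, j, k = (int(c) for c in x)
        self.phase[i, j, k] = np.int8(int(cell.phase))
        self.clock[i, j, k] = cell.cycle_clock
        self.scale[i, j, k] = cell.duration_scale
        self.fate[i, j, k] = np.int8(int(cell.fate))
        self.delay[i, j, k] = cell.death_delay
        self.arrest[i, j, k] = cell.arrest_remaining
        self.hypoxic[i, j, k] = cell.hypoxic
        self.parity[i, j, k] = np.int8(cell.division_parity % 2)

    def remove_cell(self, x: Sequence[int]) -> None:
        i, j, k = (int(c) for c in x)
        self.phase[i, j, k] = EMPTY
        self.clock[i, j, k] = 0.0
        self.scale[i, j, k] = 1.0
        self.fate[i, j, k] = 0
        self.delay[i, j, k] = 0.0
        self.arrest[i, j, k] = 0.0
        self.hypoxic[i, j, k] = False
        self.parity[i, j, k] = 0

    def iter_cells(self) -> Iterator[Tuple[Tuple[int, int, int], Cell]]:
        for i, j, k in np.argwhere(self.phase != EMPTY):
            yield (int(i), int(j), int(k)), self.get_cell((i, j, k))

    # ------------------------------------------------------------ conversions
    def state_arrays(self) -> tuple[np.ndarray, ...]:
        """The full per-voxel state, in kernel argument order."""
        return (
            self.phase,
            self.clock,
            self.scale,
            self.fate,
            self.delay,
            self.arrest,
            self.hypoxic,
            self.parity,
        )


def find_division_site(
    grid: CellGrid,
    x: Sequence[int],
    parity: int,
    rng: np.random.Generator,
) -> Optional[Tuple[int, int, int]]:
    """Empty voxel chosen for the daughter of a division attempt at ``x``.

    The neighbourhood alternates with the per-cell division parity (even ->
    Moore, odd -> von Neumann, each up to second order).  Among the empty
    in-bounds candidates the voxel nearest the centroid of the cell mass is
    selected, favouring central locations so the aggregate stays compact;
    ties are broken uniformly at random.  Returns None when every candidate
    voxel is occupied (the caller then parks the cell in G0).
    """
    x = tuple(int(c) for c in x)
    if grid.phase[x] == EMPTY:
        raise ValueError(f"no cell at {x}")
    kind = MOORE if parity % 2 == 0 else VONNEUMANN
    sites = neighbourhood_sites(x, 2, kind, grid.dims)
    empties = [s for s in sites if grid.phase[s] == EMPTY]
    if not empties:
        return None
    c = grid.centroid
    pts = np.asarray(empties, dtype=np.float64)
    d2 = ((pts - c) ** 2).sum(axis=1)
    best = d2.min()
    ties = np.flatnonzero(d2 <= best + 1e-9)
    pick = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
    return tuple(int(v) for v in empties[int(pick)])


def compact_inward(grid: CellGrid, rng: np.random.Generator) -> CellGrid:
    """Fill interior holes by shuffling cells towards the centre of mass.

    Empty voxels are visited in increasing distance from the centroid; each
    hole repeatedly exchanges with its most radially-outward occupied Moore-1
    neighbour, so the hole bubbles to the surface while cells move inward and
    the radial layering of cell states is preserved.  On return no empty voxel
    has an occupied first-order neighbour strictly farther from the centroid.
    Cell count and all per-cell state other than position are conserved.
    """
    c = grid.centroid
    if c is None:
        return grid
    seed = int(rng.integers(2**31 - 1))
    _kernels.compact(
        grid.phase,
        grid.clock,
        grid.scale,
        grid.fate,
        grid.delay,
        grid.arrest,
        grid.hypoxic,
        grid.parity,
        c[0],
        c[1],
        c[2],
        seed,
    )
    return grid


def seed_sphere(
    grid: CellGrid,
    n_cells: int,
    rng: np.random.Generator,
    phase_durations_h: Sequence[float] = DEFAULT_PHASE_DURATIONS_H,
    jitter: float = 0.1,
) -> CellGrid:
    """Initialise ``n_cells`` as a dense sphere at the lattice centre.

    The occupied voxels are the ``n_cells`` nearest the lattice centre (ties
    broken at random), each holding a viable cell in a uniformly random
    cycling phase with a uniformly random clock within that phase, mirroring
    an asynchronous exponentially growing population.
    """
    dims = np.asarray(grid.dims)
    capacity = int(np.prod(dims))
    if n_cells > capacity:
        raise ValueError(f"n_cells={n_cells} exceeds lattice capacity {capacity}")
    if n_cells == 0:
        return grid
    centre = (dims - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    d2 = (ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2
    flat = d2.ravel()
    tiebreak = rng.random(flat.size)
    order = np.lexsort((tiebreak, flat))[:n_cells]
    coords = np.column_stack(np.unravel_index(order, tuple(dims)))

    durs = np.asarray(phase_durations_h, dtype=np.float64)
    phases = rng.integers(0, 4, size=n_cells)
    scales = rng.uniform(1.0 - jitter, 1.0 + jitter, size=n_cells)
    clocks = rng.uniform(0.0, durs[phases] * scales)
    for (i, j, k), ph, sc, cl in zip(coords, phases, scales, clocks):
        grid.phase[i, j, k] = np.int8(ph)
        grid.scale[i, j, k] = sc
        grid.clock[i, j, k] = cl
    return grid


def dense_sphere_grid(
    radius_um: float,
    voxel_edge_mm: float = 0.012,
    margin: int = 3,
    dims: Optional[Tuple[int, int, int]] = None,
) -> CellGrid:
    """A grid fully occupied by viable cells within ``radius_um`` of its centre.

    Convenience constructor for idealised digital spheres used when comparing
    the lattice oxygen solver with the analytical radial model.  The lattice
    is sized to hold the sphere plus ``margin`` voxels of medium unless
    explicit ``dims`` are given.
    """
    edge_um = voxel_edge_mm * 1000.0
    r_vox = radius_um / edge_um
    if dims is None:
        n = 2 * int(np.ceil(r_vox)) + 1 + 2 * margin
        dims = (n, n, n)
    cfg = LatticeConfig(dims=dims, voxel_edge_mm=voxel_edge_mm)
    grid = CellGrid(cfg)
    centre = (np.asarray(dims) - 1) / 2.0
    ii, jj, kk = np.meshgrid(
        np.arange(dims[0]), np.arange(dims[1]), np.arange(dims[2]), indexing="ij"
    )
    d2 = (ii - centre[0]) ** 2 + (jj - centre[1]) ** 2 + (kk - centre[2]) ** 2
    grid.phase[d2 <= r_vox**2] = np.int8(int(Phase.G1))
    return grid
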