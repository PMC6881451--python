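"""Oxygen reaction-diffusion on the lattice and the analytical radial oracle.

The partial oxygen pressure ``p_O2(x)`` obeys a reaction-diffusion balance

    dp/dt = D_O2 * Laplacian(p) - Phi(x),

with ``Phi(x)`` the cellular consumption rate wherever a (non-necrotic) cell
occupies voxel ``x`` and zero elsewhere.  The medium is treated as well mixed:
every unoccupied voxel is a Dirichlet node held at the boundary pressure
(100 mmHg for spheroids in a CO2 incubator).  Because oxygen equilibrates in
seconds while the cell cycle advances in hours, only the steady state matters;
it is found by fixed-point (projected successive over-relaxation) iteration of
the 7-point-stencil discretisation until the largest per-sweep change drops
below 0.01% of the boundary pressure.  Values are clamped at zero so that
consumption stops at anoxia.

For idealised spheroids there is a closed-form radial model (Grimes et al.)
parameterised by histologically measurable lengths: the diffusion limit
``r_l``, the anoxic-core radius ``r_n`` and the outer radius ``r0``:

    p(r) = p0 * (1 + (r^2 - r0^2 + 2 r_n^3 (1/r - 1/r0)) / r_l^2),  r_n <= r <= r0

with p = 0 inside the anoxic core and ``r_l = sqrt(3 r_c^2 - 2 r_c^3 / r0)``
linking the diffusion limit to the viable-rim width ``r_c``.  This model is
the verification oracle for the lattice solver and the target of the
diffusion-coefficient fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from . import _kernels
from .lattice import CellGrid, LatticeConfig, dense_sphere_grid

__all__ = [
    "OxygenParams",
    "OxygenField",
    "AnalyticalOxygenModel",
    "ConvergenceError",
    "relax_to_equilibrium",
    "analytical_pO2",
    "diffusion_limit",
    "flag_hypoxia",
    "compare_oxygen_maps",
    "OxygenComparison",
    "fit_diffusion_coefficient",
]


class ConvergenceError(RuntimeError):
    """Raised when the relaxation fails to reach equilibrium within the cap."""


class OxygenParams(BaseModel):
    """Physical and numerical parameters of the oxygen model.

    ``d_o2_m2_s`` defaults to the fitted HCT116 value 3.8e-9 m²/s and
    ``phi_mmhg_s`` to the measured consumption rate 22.1 mmHg/s; the boundary
    pressure, hypoxia threshold and equilibrium tolerance are the standard
    spheroid-culture values (100 mmHg, 11 mmHg, 0.01%).
    """

    model_config = ConfigDict(extra="forbid")

    d_o2_m2_s: float = 3.8e-9
    phi_mmhg_s: float = 22.1
    p_boundary_mmhg: float = 100.0
    hypoxia_threshold_mmhg: float = 11.0
    convergence_tol: float = 1e-4
    max_iter: int = 200_000
    omega: float = 1.85

    @field_validator(
        "d_o2_m2_s", "phi_mmhg_s", "p_boundary_mmhg", "hypoxia_threshold_mmhg"
    )
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("oxygen parameters must be strictly positive")
        return v

    @field_validator("convergence_tol")
    @classmethod
    def _tol(cls, v: float) -> float:
        if not 0 < v < 1:
            raise ValueError("convergence_tol must be in (0, 1)")
        return v


@dataclass
class OxygenField:
    """Per-voxel partial oxygen pressure (mmHg) co-registered with a grid."""

    values: np.ndarray
    config: LatticeConfig

    def central_plane(self, axis: int = 2) -> np.ndarray:
        """The equatorial plane (mid-index slice) perpendicular to ``axis``."""
        idx = self.config.dims[axis] // 2
        return np.take(self.values, idx, axis=axis)


class AnalyticalOxygenModel(BaseModel):
    """Radial oxygenation model parameterised by measurable spheroid lengths.

    ``r_c_um`` (viable-rim width) is optional; when given it determines the
    diffusion limit through :func:`diffusion_limit` unless ``r_l_um`` is
    supplied explicitly.
    """

    model_config = ConfigDict(extra="forbid")

    p0_mmhg: float = 100.0
    r_l_um: float = 233.0
    r_n_um: float = 155.0
    r0_um: float = 250.0
    r_c_um: Optional[float] = None

    @field_validator("r_l_um")
    @classmethod
    def _rl(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("r_l_um must be > 0")
        return v

    def model_post_init(self, __context) -> None:
        if not (0 <= self.r_n_um < self.r0_um):
            raise ValueError("require 0 <= r_n < r0")

    def with_radius(self, r0_um: float) -> "AnalyticalOxygenModel":
        """Same tissue parameters for a spheroid of a different outer radius.

        Spheroids smaller than the diffusion limit cannot contain an anoxic
        core, so ``r_n`` is zeroed when ``r0 < r_l``.
        """
        r_n = self.r_n_um if r0_um >= self.r_l_um else 0.0
        r_n = min(r_n, 0.999 * r0_um)
        return AnalyticalOxygenModel(
            p0_mmhg=self.p0_mmhg, r_l_um=self.r_l_um, r_n_um=r_n, r0_um=r0_um
        )


def analytical_pO2(r_um, model: AnalyticalOxygenModel):
    """Radial partial oxygen pressure (mmHg) of the analytical model.

    Inside the anoxic core (``r < r_n``) the pressure is zero by definition;
    elsewhere the closed form is evaluated and floored at zero.  Accepts a
    scalar or array radius; raises for radii outside ``[0, r0]``.
    """
    r = np.asarray(r_um, dtype=np.float64)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    if np.any(r < 0) or np.any(r > model.r0_um * (1 + 1e-12)):
        raise ValueError("radius outside [0, r0]")
    p0, rl, rn, r0 = model.p0_mmhg, model.r_l_um, model.r_n_um, model.r0_um
    out = np.zeros_like(r)
    shell = r >= rn
    rs = r[shell]
    if rn > 0:
        core_term = 2.0 * rn**3 * (1.0 / np.maximum(rs, 1e-300) - 1.0 / r0)
    else:
        core_term = 0.0
    val = p0 * (1.0 + (rs**2 - r0**2 + core_term) / rl**2)
    out[shell] = np.maximum(val, 0.0)
    return float(out[0]) if scalar else out


def diffusion_limit(r_c_um: float, r0_um: float) -> float:
    """Diffusion limit r_l (µm) from viable-rim width and spheroid radius.

    ``r_l = sqrt(3 r_c^2 - 2 r_c^3 / r0)`` — the minimum radius of a spheroid
    whose central pressure just reaches zero.
    """
    if not 0 < r_c_um <= r0_um:
        raise ValueError("require 0 < r_c <= r0")
    arg = 3.0 * r_c_um**2 - 2.0 * r_c_um**3 / r0_um
    if arg < 0:
        raise ValueError("negative square-root argument")
    return float(np.sqrt(arg))


def relax_to_equilibrium(
    grid: CellGrid, params: OxygenParams, field: Optional[OxygenField] = None
) -> OxygenField:
    """Iterate the discrete reaction-diffusion update to its steady state.

    ``field`` may carry the previous step's solution as a warm start; the
    array is updated in place and returned wrapped in a (possibly new)
    :class:`OxygenField`.  Raises :class:`ConvergenceError` with the residual
    if the iteration cap is hit.
    """
    p_b = params.p_boundary_mmhg
    if field is None:
        p = np.full(grid.dims, p_b, dtype=np.float64)
    else:
        p = field.values
    occ = grid.occupied
    p[~occ] = p_b
    if not occ.any():
        return OxygenField(p, grid.config)
    h_m = grid.config.voxel_edge_mm * 1e-3
    cons_term = h_m**2 * params.phi_mmhg_s / params.d_o2_m2_s
    x0, x1, y0, y1, z0, z1 = grid.bounding_box()
    iters, residual = _kernels.relax(
        p,
        grid.consuming.astype(np.uint8),
        occ.astype(np.uint8),
        x0,
        x1,
        y0,
        y1,
        z0,
        z1,
        cons_term,
        p_b,
        params.convergence_tol * p_b,
        params.omega,
        params.max_iter,
    )
    if iters < 0:
        raise ConvergenceError(
            f"oxygen relaxation did not converge in {params.max_iter} sweeps "
            f"(residual {residual:.3g} mmHg)"
        )
    return OxygenField(p, grid.config)


def flag_hypoxia(field: OxygenField, grid: CellGrid, threshold_mmhg: float = 11.0) -> CellGrid:
    """Label cells hypoxic where pO2 falls strictly below the threshold.

    Cells returning to or above the threshold are unflagged; necrotic voxels
    carry no flag.
    """
    alive = grid.consuming
    grid.hypoxic[...] = alive & (field.values < threshold_mmhg)
    return grid


@dataclass
class OxygenComparison:
    """Central-plane difference between the lattice solver and the radial model.

    ``max_rel_diff_pct`` is the maximum |analytic - simulated| in % of p0 over
    the region where the radial model is a prediction (r_n <= r <= r0; inside
    the anoxic core the model *defines* p = 0 as its inner boundary rather
    than predicting it).  ``max_rel_diff_pct_full`` covers every occupied
    voxel of the plane, with the core taken as 0 and radii beyond r0 as p0.
    """

    max_rel_diff_pct: float
    max_rel_diff_pct_full: float
    mean_rel_diff_pct: float
    n_compared: int
    plane_axis: int
    plane_index: int
    diff_map_pct: np.ndarray


def compare_oxygen_maps(
    sim: OxygenField,
    model: AnalyticalOxygenModel,
    grid: CellGrid,
    axis: int = 2,
) -> OxygenComparison:
    """Compare a solved oxygen field with the analytical radial model.

    The central equatorial plane is extracted, each occupied voxel is assigned
    the analytic value at its radius from the cell-mass centroid (p0 beyond
    r0, 0 inside the anoxic core), and per-voxel relative differences are
    reported in % of p0.
    """
    if grid.n_cells == 0:
        raise ValueError("grid is empty")
    idx = grid.dims[axis] // 2
    plane_p = np.take(sim.values, idx, axis=axis)
    plane_occ = np.take(grid.occupied, idx, axis=axis)
    c = grid.centroid
    edge = grid.config.voxel_edge_um
    axes = [a for a in range(3) if a != axis]
    n0, n1 = plane_p.shape
    i0, i1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
    r_um = (
        np.sqrt(
            (i0 - c[axes[0]]) ** 2 + (i1 - c[axes[1]]) ** 2 + (idx - c[axis]) ** 2
        )
        * edge
    )
    analytic = np.full_like(plane_p, model.p0_mmhg)
    inside = r_um <= model.r0_um
    analytic[inside] = analytical_pO2(r_um[inside], model)
    diff_pct = np.where(plane_occ, np.abs(analytic - plane_p) / model.p0_mmhg * 100.0, np.nan)
    in_domain = plane_occ & inside & (r_um >= model.r_n_um)
    if not in_domain.any():
        in_domain = plane_occ
    max_domain = float(np.nanmax(np.where(in_domain, diff_pct, np.nan)))
    max_full = float(np.nanmax(diff_pct))
    mean_domain = float(np.nanmean(np.where(in_domain, diff_pct, np.nan)))
    return OxygenComparison(
        max_rel_diff_pct=max_domain,
        max_rel_diff_pct_full=max_full,
        mean_rel_diff_pct=mean_domain,
        n_compared=int(in_domain.sum()),
        plane_axis=axis,
        plane_index=idx,
        diff_map_pct=diff_pct,
    )


def fit_diffusion_coefficient(
    radii_um: Sequence[float],
    model: AnalyticalOxygenModel,
    params: OxygenParams,
    search_grid: Sequence[float],
    voxel_edge_mm: float = 0.012,
    return_trace: bool = False,
):
    """Grid-search the diffusion coefficient against the radial model.

    For each candidate D the equilibrium field is solved on ideal dense
    spheres of the given radii and the summed squared central-plane
    difference to the analytic model (over its validity domain, in % of p0)
    is accumulated; the candidate minimising the total is returned.  The
    tissue parameters (p0, r_l, r_n) come from ``model``; the outer radius is
    set per sphere with the anoxic core zeroed for spheroids below the
    diffusion limit.
    """
    cands = list(search_grid)
    if not cands:
        raise ValueError("empty search grid")
    sses = []
    for d in cands:
        p = params.model_copy(update={"d_o2_m2_s": float(d)})
        total = 0.0
        for r0 in radii_um:
            grid = dense_sphere_grid(r0, voxel_edge_mm=voxel_edge_mm)
            fld = relax_to_equilibrium(grid, p)
            m = model.with_radius(r0)
            cmpd = compare_oxygen_maps(fld, m, grid)
            idx = grid.dims[2] // 2
            plane_occ = np.take(grid.occupied, idx, axis=2)
            d_map = cmpd.diff_map_pct
            # restrict to the model's validity annulus, as in the summary
            c = grid.centroid
            edge = grid.config.voxel_edge_um
            n0, n1 = d_map.shape
            i0, i1 = np.meshgrid(np.arange(n0), np.arange(n1), indexing="ij")
            r_um = (
                np.sqrt((i0 - c[0]) ** 2 + (i1 - c[1]) ** 2 + (idx - c[2]) ** 2) * edge
            )
            mask = plane_occ & (r_um >= m.r_n_um) & (r_um <= m.r0_um)
            total += float(np.nansum(np.where(mask, d_map, 0.0) ** 2))
        sses.append(total)
    best = cands[int(np.argmin(sses))]
    if return_trace:
        return best, {"d_o2_m2_s": cands, "sse": sses}
    return best
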