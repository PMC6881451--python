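"""Survival models and cell-death cascades for radiation and hyperthermia.

Radiation uses the linear-quadratic clonogenic model with a cell-cycle weight
``gamma`` and the oxygen enhancement ratio applied to the dose,

    S_RT = exp(-gamma * (alpha * d_OER + beta * d_OER^2)),   d_OER = d / OER(pO2),

with OER = 1 above 11 mmHg and 3 - 2*pO2/11 below (anoxic limit 3), so hypoxic
cells are radioprotected.  Cells losing the survival draw are labelled dying
but persist until a division attempt, where they undergo mitotic catastrophe
with probability ``p_mitoticDeath`` (a smaller value during the first
``t_delayRT`` days reproduces the experimentally observed response delay) or
otherwise produce two dying daughters.

Hyperthermia survival follows the AlphaR thermal-dose model (quadratic below
the transition dose D_T = alpha0 / (2 beta_HT), linear above, continuous in
value and slope at D_T) capped by a plateau surviving fraction above
160 CEM43, as observed for spheroids.  Heat death is proliferation
*independent*: dying cells are removed after a normally distributed delay
regardless of position, transiently loosening the spheroid and letting
quiescent cells reoxygenate and re-enter the cycle, while survivors resume
after a uniformly distributed cycle arrest.

Combination treatments chain the two cascades: a fraction 1 - S_RTHT (the LQ
model with thermal-dose dependent alpha, beta) takes the radiation death
route, a further 1 - S_HT of the rest takes the heat death route, and the
remaining S_RTHT * S_HT survive with a cycle arrest.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator

from .lattice import CellGrid, Fate, Phase
from .oxygen import OxygenField

__all__ = [
    "RTParams",
    "HTParams",
    "RTHTParams",
    "TreatmentParams",
    "oer",
    "survival_rt",
    "survival_ht_monolayer",
    "survival_ht_spheroid",
    "apply_radiation",
    "resolve_mitotic_fate",
    "apply_hyperthermia",
    "apply_combination",
]

#: pO2 (mmHg) above which radiosensitivity is fully oxic
OER_THRESHOLD_MMHG = 11.0


def _default_gamma_ht() -> Tuple[float, float, float, float, float]:
    # Cycling weights in fixed ratio gamma_G1 : gamma_S : gamma_G2 = 1.5^2 : 1.5 : 1
    # (M treated like G2), normalised so the cycling mean is 1; G0 cells are
    # three-fold heat resistant, applied on the exponent (-ln S scaled by 1/3).
    base = np.array([2.25, 1.5, 1.0, 1.0])
    base = base / base.mean()
    return (float(base[0]), float(base[1]), float(base[2]), float(base[3]), 1.0 / 3.0)


class RTParams(BaseModel):
    """Radiation survival and death-cascade parameters.

    ``alpha_per_gy`` / ``beta_per_gy2`` and the per-phase gammas are cell-line
    inputs (the defaults are illustrative placeholders, not measured HCT116
    values).  The two-stage mitotic-death probabilities and the switch time
    are the fitted spheroid-response values (0.44 within 3.5 days of
    exposure, 0.59 thereafter).
    """

    model_config = ConfigDict(extra="forbid")

    alpha_per_gy: float = 0.2
    beta_per_gy2: float = 0.02
    #: weights for (G1, S, G2, M, G0)
    gamma_by_phase: Tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    p_mitotic_death_early: float = 0.44
    p_mitotic_death_late: float = 0.59
    t_delay_rt_days: float = 3.5

    @field_validator("alpha_per_gy", "beta_per_gy2")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("LQ parameters must be >= 0")
        return v

    @field_validator("p_mitotic_death_early", "p_mitotic_death_late")
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0 <= v <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @field_validator("t_delay_rt_days")
    @classmethod
    def _delay(cls, v: float) -> float:
        if v < 0:
            raise ValueError("t_delay_rt_days must be >= 0")
        return v

    def p_mitotic_death(self, t_since_rt_days: float) -> float:
        return (
            self.p_mitotic_death_early
            if t_since_rt_days <= self.t_delay_rt_days
            else self.p_mitotic_death_late
        )


class HTParams(BaseModel):
    """Hyperthermia survival and death-cascade parameters.

    ``alpha0_per_cem43`` / ``beta_ht_per_cem43_2`` are the monolayer AlphaR
    parameters (illustrative defaults, not measured values); the plateau
    fraction 0.0005 above 160 CEM43, the 96 h mean death delay and the 30 h
    mean cycle arrest are the fitted spheroid values.  The delay is drawn
    from a normal distribution truncated at zero (sd defaults to mean/4) and
    the arrest from Uniform(0, 2*mean).
    """

    model_config = ConfigDict(extra="forbid")

    alpha0_per_cem43: float = 0.1
    beta_ht_per_cem43_2: float = 0.001
    gamma_ht_by_phase: Tuple[float, float, float, float, float] = _default_gamma_ht()
    #: how the three-fold G0 resistance is applied: on the exponent (-ln S)
    #: or directly on the surviving fraction
    g0_resistance_semantics: str = "exponent"
    s_plateau: float = 0.0005
    plateau_threshold_cem43: float = 160.0
    t_delay_ht_to_death_mean_h: float = 96.0
    t_delay_ht_to_death_sd_h: Optional[float] = None
    t_cell_cycle_arrest_mean_h: float = 30.0

    @field_validator("s_plateau")
    @classmethod
    def _plateau(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("s_plateau must lie in (0, 1]")
        return v

    @field_validator("t_delay_ht_to_death_mean_h", "t_cell_cycle_arrest_mean_h")
    @classmethod
    def _times(cls, v: float) -> float:
        if v < 0:
            raise ValueError("times must be >= 0")
        return v

    @field_validator("g0_resistance_semantics")
    @classmethod
    def _sem(cls, v: str) -> str:
        if v not in ("exponent", "survival"):
            raise ValueError("g0_resistance_semantics must be 'exponent' or 'survival'")
        return v

    @property
    def delay_sd_h(self) -> float:
        if self.t_delay_ht_to_death_sd_h is not None:
            return self.t_delay_ht_to_death_sd_h
        return self.t_delay_ht_to_death_mean_h / 4.0


class RTHTParams(BaseModel):
    """Thermal-dose dependence of the LQ parameters for combined treatment.

    Lookup tables interpolated linearly in t43; the zero-dose entries must
    reproduce the radiation-only alpha and beta.  The default tables are
    illustrative (roughly linear radiosensitisation with thermal dose), not
    measured values.
    """

    model_config = ConfigDict(extra="forbid")

    t43_knots: Tuple[float, ...] = (0.0, 40.0, 80.0, 160.0, 240.0)
    alpha_values: Tuple[float, ...] = (0.2, 0.27, 0.33, 0.47, 0.6)
    beta_values: Tuple[float, ...] = (0.02, 0.027, 0.033, 0.047, 0.06)

    def model_post_init(self, __context) -> None:
        if not (len(self.t43_knots) == len(self.alpha_values) == len(self.beta_values)):
            raise ValueError("knot and value tables must have equal length")
        if list(self.t43_knots) != sorted(self.t43_knots):
            raise ValueError("t43_knots must be non-decreasing")

    def alpha(self, t43: float) -> float:
        return float(np.interp(t43, self.t43_knots, self.alpha_values))

    def beta(self, t43: float) -> float:
        return float(np.interp(t43, self.t43_knots, self.beta_values))


class TreatmentParams(BaseModel):
    """Bundle of the treatment parameterisations a schedule may reference."""

    model_config = ConfigDict(extra="forbid")

    rt: Optional[RTParams] = None
    ht: Optional[HTParams] = None
    rtht: Optional[RTHTParams] = None


def oer(pO2_mmhg):
    """Oxygen enhancement ratio: 1 when oxic, rising linearly to 3 at anoxia."""
    p = np.asarray(pO2_mmhg, dtype=np.float64)
    if np.any(p < 0):
        raise ValueError("pO2 must be >= 0")
    out = np.where(
        p > OER_THRESHOLD_MMHG, 1.0, 3.0 - 2.0 * p / OER_THRESHOLD_MMHG
    )
    return float(out) if out.ndim == 0 else out


def survival_rt(d_gy, pO2_mmhg, phase, p: RTParams):
    """LQ surviving fraction after dose ``d`` at the cell's oxygenation/phase."""
    d = np.asarray(d_gy, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    gamma = _gamma_of(phase, p.gamma_by_phase)
    d_eff = d / oer(pO2_mmhg)
    s = np.exp(-gamma * (p.alpha_per_gy * d_eff + p.beta_per_gy2 * d_eff**2))
    return float(s) if np.ndim(s) == 0 else s


def _gamma_of(phase, table):
    """Per-cell weight from a (G1, S, G2, M, G0) table."""
    ph = np.asarray(phase, dtype=np.int64)
    tab = np.asarray(table, dtype=np.float64)
    if np.any((ph < 0) | (ph > 4)):
        raise ValueError("phase must be a cycling phase or G0")
    out = tab[ph]
    return float(out) if out.ndim == 0 else out


def _neg_log_s_ht(t43: float, p: HTParams) -> float:
    """Phase-free AlphaR exponent -ln S(t43) (gamma applied by callers)."""
    if t43 < 0:
        raise ValueError("thermal dose must be >= 0")
    a0, b = p.alpha0_per_cem43, p.beta_ht_per_cem43_2
    if b <= 0:
        if a0 == 0:
            return 0.0
        raise ValueError("beta_HT must be > 0 when alpha0 > 0 (degenerate AlphaR model)")
    d_t = a0 / (2.0 * b)
    if t43 <= d_t:
        return b * t43**2
    return a0 * t43 - a0**2 / (4.0 * b)


def survival_ht_monolayer(t43: float, p: HTParams, phase=Phase.G1):
    """AlphaR monolayer surviving fraction with cycle-stage weighting.

    The natural-log exponent is ``gamma_HT * (beta_HT t43^2)`` below
    D_T = alpha0/(2 beta_HT) and ``gamma_HT * (alpha0 t43 - alpha0^2/(4 beta_HT))``
    above; the branches join continuously in value and slope.
    """
    nls = _neg_log_s_ht(float(t43), p)
    ph = np.asarray(phase, dtype=np.int64)
    if p.g0_resistance_semantics == "survival" and np.ndim(ph) == 0 and int(ph) == int(Phase.G0):
        gam = np.asarray(p.gamma_ht_by_phase[:4], dtype=np.float64)
        s_cycling = float(np.exp(-gam * nls).mean())
        return min(1.0, 3.0 * s_cycling)
    gamma = _gamma_of(phase, p.gamma_ht_by_phase)
    s = np.exp(-gamma * nls)
    return float(s) if np.ndim(s) == 0 else s


def survival_ht_spheroid(t43: float, p: HTParams, phase=Phase.G1):
    """Spheroid surviving fraction: AlphaR below 160 CEM43, plateau above.

    The plateau reflects the enhanced thermal resistance of cells heated in
    3D context; it overrides the phase weighting (a single fraction for the
    whole population).
    """
    if t43 < 0:
        raise ValueError("thermal dose must be >= 0")
    if t43 > p.plateau_threshold_cem43:
        s = np.full(np.shape(phase), p.s_plateau) if np.ndim(phase) else p.s_plateau
        return s
    return survival_ht_monolayer(t43, p, phase)


# --------------------------------------------------------------------- events

def _viable_cells(grid: CellGrid) -> np.ndarray:
    """Coordinates of cells eligible for a new treatment label."""
    mask = grid.consuming & (grid.fate == int(Fate.VIABLE))
    return np.argwhere(mask)


def apply_radiation(
    grid: CellGrid,
    d_gy: float,
    p: RTParams,
    field: OxygenField,
    rng: np.random.Generator,
) -> CellGrid:
    """Label a fraction 1 - S_RT of cells as dying by mitotic catastrophe.

    Each cell draws N ~ U(0,1) against its own surviving fraction (dose
    weighted by the OER at its voxel, gamma by its phase).  Survivors keep
    proliferating with no cycle delay; the exposure time is recorded for the
    two-stage mitotic-death clock.
    """
    if d_gy < 0:
        raise ValueError("dose must be >= 0")
    coords = _viable_cells(grid)
    grid.rt_time_h = grid.t_h
    if coords.size == 0:
        return grid
    i, j, k = coords.T
    s = survival_rt(d_gy, field.values[i, j, k], grid.phase[i, j, k], p)
    losers = rng.random(len(coords)) > s
    grid.fate[i[losers], j[losers], k[losers]] = np.int8(int(Fate.DYING_RT))
    return grid


def resolve_mitotic_fate(
    t_since_rt_days: float, p: RTParams, rng: np.random.Generator
) -> str:
    """Outcome of a division attempt by a dying irradiated cell.

    Returns ``"death"`` (mitotic catastrophe, the cell is removed) with the
    stage-appropriate probability, else ``"division"`` (two dying daughters).
    """
    p_mit = p.p_mitotic_death(t_since_rt_days)
    return "death" if rng.random() < p_mit else "division"


def apply_hyperthermia(
    grid: CellGrid, t43: float, p: HTParams, rng: np.random.Generator
) -> CellGrid:
    """Partition heated cells into delayed-death and arrested-survivor pools.

    Dying cells get a death delay ~ Normal(mean, sd) truncated at zero and
    are removed when it expires regardless of position; survivors get a cycle
    arrest ~ Uniform(0, 2*mean).  Reoxygenation and quiescence reactivation
    then emerge from the ordinary step loop.
    """
    if t43 < 0:
        raise ValueError("thermal dose must be >= 0")
    coords = _viable_cells(grid)
    if coords.size == 0 or t43 == 0:
        return grid
    i, j, k = coords.T
    phases = grid.phase[i, j, k].astype(np.int64)
    s_by_phase = np.asarray(
        [survival_ht_spheroid(t43, p, ph) for ph in range(5)], dtype=np.float64
    )
    s = s_by_phase[phases]
    n = rng.random(len(coords))
    losers = n > s
    delays = np.maximum(
        rng.normal(p.t_delay_ht_to_death_mean_h, p.delay_sd_h, size=int(losers.sum())),
        0.0,
    )
    grid.fate[i[losers], j[losers], k[losers]] = np.int8(int(Fate.DYING_HT))
    grid.delay[i[losers], j[losers], k[losers]] = delays
    surv = ~losers
    arrests = rng.uniform(0.0, 2.0 * p.t_cell_cycle_arrest_mean_h, size=int(surv.sum()))
    grid.arrest[i[surv], j[surv], k[surv]] = arrests
    return grid


def apply_combination(
    grid: CellGrid,
    d_gy: float,
    t43: float,
    rp: RTParams,
    hp: HTParams,
    cp: RTHTParams,
    field: OxygenField,
    rng: np.random.Generator,
) -> CellGrid:
    """Simultaneous radiation + heat: chained survival cascade.

    Per cell: N > S_RTHT (LQ with alpha(t43), beta(t43)) sends it down the
    radiation death route; otherwise N2 > S_HT sends it down the heat death
    route; the rest survive with a heat-induced cycle arrest, so the expected
    surviving fraction is S_RTHT * S_HT.
    """
    if d_gy < 0 or t43 < 0:
        raise ValueError("dose and thermal dose must be >= 0")
    if abs(cp.alpha(0.0) - rp.alpha_per_gy) > 1e-9 or abs(cp.beta(0.0) - rp.beta_per_gy2) > 1e-9:
        raise ValueError(
            "thermal-dose tables must reduce to the radiation-only alpha/beta at t43 = 0"
        )
    coords = _viable_cells(grid)
    grid.rt_time_h = grid.t_h
    if coords.size == 0:
        return grid
    rp_t = rp.model_copy(
        update={"alpha_per_gy": cp.alpha(t43), "beta_per_gy2": cp.beta(t43)}
    )
    i, j, k = coords.T
    phases = grid.phase[i, j, k]
    s_rtht = survival_rt(d_gy, field.values[i, j, k], phases, rp_t)
    n1 = rng.random(len(coords))
    rt_route = n1 > s_rtht
    grid.fate[i[rt_route], j[rt_route], k[rt_route]] = np.int8(int(Fate.DYING_RT))

    rest = ~rt_route
    if t43 > 0 and rest.any():
        ri, rj, rk = i[rest], j[rest], k[rest]
        s_by_phase = np.asarray(
            [survival_ht_spheroid(t43, hp, ph) for ph in range(5)], dtype=np.float64
        )
        s_ht = s_by_phase[phases[rest].astype(np.int64)]
        n2 = rng.random(int(rest.sum()))
        ht_route = n2 > s_ht
        delays = np.maximum(
            rng.normal(hp.t_delay_ht_to_death_mean_h, hp.delay_sd_h, size=int(ht_route.sum())),
            0.0,
        )
        grid.fate[ri[ht_route], rj[ht_route], rk[ht_route]] = np.int8(int(Fate.DYING_HT))
        grid.delay[ri[ht_route], rj[ht_route], rk[ht_route]] = delays
        surv = ~ht_route
        grid.arrest[ri[surv], rj[surv], rk[surv]] = rng.uniform(
            0.0, 2.0 * hp.t_cell_cycle_arrest_mean_h, size=int(surv.sum())
        )
    return grid
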