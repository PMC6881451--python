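"""Independent oracles used by the test suite.

These deliberately avoid the package's own numerical paths: brute-force
neighbourhood enumeration, and a 1D spherical-coordinate steady-state
finite-difference solution of the oxygen reaction-diffusion balance.
"""
import numpy as np


def brute_force_offsets(order: int, kind: str) -> set:
    """Enumerate neighbourhood offsets directly from the metric definition."""
    out = set()
    for dx in range(-order, order + 1):
        for dy in range(-order, order + 1):
            for dz in range(-order, order + 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if kind == "MOORE" and max(abs(dx), abs(dy), abs(dz)) <= order:
                    out.add((dx, dy, dz))
                if kind == "VONNEUMANN" and abs(dx) + abs(dy) + abs(dz) <= order:
                    out.add((dx, dy, dz))
    return out


def solve_radial_steady_state(
    r0_um: float,
    d_m2_s: float,
    phi_mmhg_s: float,
    p0_mmhg: float = 100.0,
    dr_um: float = 4.0,
):
    """Steady state of D*(p'' + 2 p'/r) = Phi on [0, r0], p(r0) = p0, p'(0) = 0.

    Finite differences on a uniform radial mesh with flux form
    (r^2 p')' / r^2; consumption is switched off on nodes driven below zero
    (active-set iteration for the anoxic obstacle).  Returns (r_um, p_mmhg).
    """
    n = int(round(r0_um / dr_um))
    dr = dr_um * 1e-6
    r = np.arange(n + 1) * dr
    consume = np.ones(n + 1, dtype=bool)
    p = np.full(n + 1, p0_mmhg)
    for _ in range(100):
        a = np.zeros((n, n))
        rhs = np.zeros(n)
        for i in range(n):
            src = (phi_mmhg_s / d_m2_s) * dr * dr if consume[i] else 0.0
            if i == 0:
                # p'(0)=0; Laplacian at the origin ~ 6 (p1 - p0) / dr^2
                a[0, 0] = -6.0
                a[0, 1] = 6.0
                rhs[0] = src
            else:
                rm = (r[i] - dr / 2.0) ** 2 / r[i] ** 2
                rp = (r[i] + dr / 2.0) ** 2 / r[i] ** 2
                a[i, i - 1] = rm
                a[i, i] = -(rm + rp)
                if i + 1 < n:
                    a[i, i + 1] = rp
                    rhs[i] = src
                else:
                    rhs[i] = src - rp * p0_mmhg
        sol = np.linalg.solve(a, rhs)
        p = np.append(sol, p0_mmhg)
        new_consume = p > 0
        new_consume[-1] = True
        if np.array_equal(new_consume, consume):
            break
        consume = new_consume
    return r * 1e6, np.maximum(p, 0.0)


def shell_profile(grid, field, bin_width_vox: float = 1.0):
    """Shell-averaged radial profile of a lattice oxygen field (r in um)."""
    coords = np.argwhere(grid.occupied)
    c = coords.mean(axis=0)
    d_vox = np.sqrt(((coords - c) ** 2).sum(axis=1))
    vals = field.values[tuple(coords.T)]
    bins = np.arange(0, d_vox.max() + bin_width_vox, bin_width_vox)
    idx = np.digitize(d_vox, bins)
    centres, means = [], []
    for b in range(1, len(bins) + 1):
        m = idx == b
        if m.any():
            centres.append(d_vox[m].mean() * grid.config.voxel_edge_um)
            means.append(vals[m].mean())
    return np.asarray(centres), np.asarray(means)
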