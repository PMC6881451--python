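"""Numba kernels for the hot loops of the cellular automaton.

Phase codes: -1 empty, 0 G1, 1 S, 2 G2, 3 M, 4 G0, 5 necrotic.
Fate codes: 0 viable, 1 dying (radiation), 2 dying (hyperthermia).

All stochastic draws inside a kernel use numba's ``np.random`` stream, seeded
once per call from the caller's Generator; together with the caller-supplied
visit order this makes every simulation bit-reproducible for a given seed.
"""
import numpy as np
from numba import njit

EMPTY = -1
G1 = 0
S = 1
G2 = 2
M = 3
G0 = 4
NEC = 5

VIABLE = 0
DYING_RT = 1
DYING_HT = 2


@njit(cache=True)
def relax(p, consume, occupied, x0, x1, y0, y1, z0, z1, cons_term, p_b, tol, omega, max_iter):
    """Projected SOR relaxation of the steady oxygen reaction-diffusion field.

    Solves the 7-point-stencil discretisation of D*Laplacian(p) = Phi on the
    occupied voxels, with every unoccupied voxel held at the medium pressure
    ``p_b`` (Dirichlet) and values clamped to [0, p_b]; the lower clamp stops
    consumption at anoxia.  ``cons_term`` is h^2*Phi/D in mmHg.  Iterates
    until the largest per-sweep change is <= ``tol`` (mmHg).

    Returns (iterations, last_max_change); iterations is -1 on hitting the cap.
    """
    nx, ny, nz = p.shape
    maxd = 0.0
    for it in range(max_iter):
        maxd = 0.0
        for i in range(x0, x1):
            for j in range(y0, y1):
                for k in range(z0, z1):
                    if occupied[i, j, k] == 0:
                        continue
                    s = 0.0
                    if i > 0:
                        s += p[i - 1, j, k]
                    else:
                        s += p_b
                    if i < nx - 1:
                        s += p[i + 1, j, k]
                    else:
                        s += p_b
                    if j > 0:
                        s += p[i, j - 1, k]
                    else:
                        s += p_b
                    if j < ny - 1:
                        s += p[i, j + 1, k]
                    else:
                        s += p_b
                    if k > 0:
                        s += p[i, j, k - 1]
                    else:
                        s += p_b
                    if k < nz - 1:
                        s += p[i, j, k + 1]
                    else:
                        s += p_b
                    target = (s - cons_term * consume[i, j, k]) / 6.0
                    new = p[i, j, k] + omega * (target - p[i, j, k])
                    if new < 0.0:
                        new = 0.0
                    elif new > p_b:
                        new = p_b
                    d = new - p[i, j, k]
                    if d < 0.0:
                        d = -d
                    if d > maxd:
                        maxd = d
                    p[i, j, k] = new
        if maxd <= tol:
            return it + 1, maxd
    return -1, maxd


@njit(cache=True)
def _division_site(phase, cx, cy, cz, x, y, z, offs):
    """Nearest-to-centroid empty voxel among ``offs`` around (x,y,z).

    Ties broken uniformly via reservoir sampling.  Returns (i,j,k) or
    (-1,-1,-1) when no candidate is free.
    """
    nx, ny, nz = phase.shape
    best = 1.0e30
    bi = -1
    bj = -1
    bk = -1
    nties = 0
    for n in range(offs.shape[0]):
        i = x + offs[n, 0]
        j = y + offs[n, 1]
        k = z + offs[n, 2]
        if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
            continue
        if phase[i, j, k] != EMPTY:
            continue
        d = (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2
        if d < best - 1e-9:
            best = d
            bi, bj, bk = i, j, k
            nties = 1
        elif d <= best + 1e-9:
            nties += 1
            if np.random.random() < 1.0 / nties:
                bi, bj, bk = i, j, k
    return bi, bj, bk


@njit(cache=True)
def _clear_voxel(phase, clock, scale, fate, delay, arrest, hypoxic, parity, i, j, k):
    phase[i, j, k] = EMPTY
    clock[i, j, k] = 0.0
    scale[i, j, k] = 1.0
    fate[i, j, k] = VIABLE
    delay[i, j, k] = 0.0
    arrest[i, j, k] = 0.0
    hypoxic[i, j, k] = False
    parity[i, j, k] = 0


@njit(cache=True)
def step_cells(
    phase,
    clock,
    scale,
    fate,
    delay,
    arrest,
    hypoxic,
    parity,
    born,
    xs,
    ys,
    zs,
    cx,
    cy,
    cz,
    dur_h,
    dt,
    p_hypoxia_death,
    p_clear_necrotic,
    p_mitotic_death,
    jitter,
    hypoxic_arrest,
    moore2,
    vn2,
    seed,
):
    """One CA time step over the cells listed in (xs, ys, zs) (pre-permuted).

    Per cell, in order: hypoxia-induced necrosis, necrotic clearance, delayed
    heat death, then cycle progression with division / quiescence handling.
    ``born`` is a scratch mask marking daughters created this step so they do
    not act before their first full step.  Returns (divisions, removals).
    """
    np.random.seed(seed)
    n_div = 0
    n_rem = 0
    for n in range(xs.size):
        x = xs[n]
        y = ys[n]
        z = zs[n]
        ph = phase[x, y, z]
        if ph == EMPTY or born[x, y, z]:
            continue
        # hypoxia-induced death (viable and treatment-labelled cells alike)
        if ph != NEC and hypoxic[x, y, z]:
            if np.random.random() < p_hypoxia_death:
                phase[x, y, z] = NEC
                fate[x, y, z] = VIABLE
                delay[x, y, z] = 0.0
                arrest[x, y, z] = 0.0
                ph = NEC
        # necrotic clearance
        if ph == NEC:
            if np.random.random() < p_clear_necrotic:
                _clear_voxel(phase, clock, scale, fate, delay, arrest, hypoxic, parity, x, y, z)
                n_rem += 1
            continue
        # delayed heat-induced death: committed cells only count down
        if fate[x, y, z] == DYING_HT:
            delay[x, y, z] -= dt
            if delay[x, y, z] <= 0.0:
                _clear_voxel(phase, clock, scale, fate, delay, arrest, hypoxic, parity, x, y, z)
                n_rem += 1
            continue
        # post-treatment cycle arrest
        if arrest[x, y, z] > 0.0:
            arrest[x, y, z] -= dt
            if arrest[x, y, z] < 0.0:
                arrest[x, y, z] = 0.0
            continue
        # hypoxic cells pause cycle progression (reversible quiescence)
        if hypoxic_arrest and hypoxic[x, y, z]:
            continue

        attempt = False
        if ph == G0:
            attempt = True  # re-entry: look for freed space every step
        else:
            c = clock[x, y, z] + dt
            sc = scale[x, y, z]
            while ph < M and c >= dur_h[ph] * sc - 1e-9:
                c -= dur_h[ph] * sc
                ph += 1
            if ph == M and c >= dur_h[M] * sc - 1e-9:
                attempt = True
            phase[x, y, z] = ph
            clock[x, y, z] = c

        if attempt:
            par = parity[x, y, z]
            parity[x, y, z] = (par + 1) % 2
            if par % 2 == 0:
                si, sj, sk = _division_site(phase, cx, cy, cz, x, y, z, moore2)
            else:
                si, sj, sk = _division_site(phase, cx, cy, cz, x, y, z, vn2)
            if si < 0:
                phase[x, y, z] = G0
                clock[x, y, z] = 0.0
            else:
                if fate[x, y, z] == DYING_RT and np.random.random() < p_mitotic_death:
                    # mitotic catastrophe: cell dies at the division attempt
                    _clear_voxel(
                        phase, clock, scale, fate, delay, arrest, hypoxic, parity, x, y, z
                    )
                    n_rem += 1
                else:
                    # successful division: mother resets, daughter placed
                    phase[x, y, z] = G1
                    clock[x, y, z] = 0.0
                    scale[x, y, z] = 1.0 - jitter + 2.0 * jitter * np.random.random()
                    phase[si, sj, sk] = G1
                    clock[si, sj, sk] = 0.0
                    scale[si, sj, sk] = 1.0 - jitter + 2.0 * jitter * np.random.random()
                    fate[si, sj, sk] = fate[x, y, z]
                    delay[si, sj, sk] = 0.0
                    arrest[si, sj, sk] = 0.0
                    hypoxic[si, sj, sk] = False
                    parity[si, sj, sk] = parity[x, y, z]
                    born[si, sj, sk] = True
                    n_div += 1
    return n_div, n_rem


@njit(cache=True)
def compact(phase, clock, scale, fate, delay, arrest, hypoxic, parity, cx, cy, cz, seed):
    """Inward compaction: bubble interior holes outward to the surface.

    Empty voxels (in increasing distance from the centroid) repeatedly swap
    with their most radially-outward occupied Moore-1 neighbour until no
    occupied neighbour lies strictly farther out.  Each swap moves a cell
    strictly inward, so the total squared radial moment decreases and the
    sweep terminates.  Repeats passes until a full pass makes no move.
    Returns the number of cell moves performed.
    """
    np.random.seed(seed)
    nx, ny, nz = phase.shape
    total = 0
    while True:
        # bounding box of the occupied region
        x0, x1 = nx, -1
        y0, y1 = ny, -1
        z0, z1 = nz, -1
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    if phase[i, j, k] != EMPTY:
                        if i < x0:
                            x0 = i
                        if i > x1:
                            x1 = i
                        if j < y0:
                            y0 = j
                        if j > y1:
                            y1 = j
                        if k < z0:
                            z0 = k
                        if k > z1:
                            z1 = k
        if x1 < 0:
            return total
        # collect empties in the box, sorted by distance to centroid
        count = 0
        for i in range(x0, x1 + 1):
            for j in range(y0, y1 + 1):
                for k in range(z0, z1 + 1):
                    if phase[i, j, k] == EMPTY:
                        count += 1
        if count == 0:
            return total
        exs = np.empty(count, dtype=np.int64)
        eys = np.empty(count, dtype=np.int64)
        ezs = np.empty(count, dtype=np.int64)
        ed2 = np.empty(count, dtype=np.float64)
        m = 0
        for i in range(x0, x1 + 1):
            for j in range(y0, y1 + 1):
                for k in range(z0, z1 + 1):
                    if phase[i, j, k] == EMPTY:
                        exs[m] = i
                        eys[m] = j
                        ezs[m] = k
                        ed2[m] = (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2
                        m += 1
        order = np.argsort(ed2)
        moved = 0
        for nidx in range(count):
            e = order[nidx]
            hx = exs[e]
            hy = eys[e]
            hz = ezs[e]
            if phase[hx, hy, hz] != EMPTY:
                continue
            while True:
                dh = (hx - cx) ** 2 + (hy - cy) ** 2 + (hz - cz) ** 2
                best = 0.0
                bi = -1
                bj = -1
                bk = -1
                nties = 0
                for dx in range(-1, 2):
                    for dy in range(-1, 2):
                        for dz in range(-1, 2):
                            if dx == 0 and dy == 0 and dz == 0:
                                continue
                            i = hx + dx
                            j = hy + dy
                            k = hz + dz
                            if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                                continue
                            if phase[i, j, k] == EMPTY:
                                continue
                            gain = (i - cx) ** 2 + (j - cy) ** 2 + (k - cz) ** 2 - dh
                            if gain <= 1e-9:
                                continue
                            if bi < 0 or gain > best + 1e-9:
                                best = gain
                                bi, bj, bk = i, j, k
                                nties = 1
                            elif gain > best - 1e-9:
                                nties += 1
                                if np.random.random() < 1.0 / nties:
                                    bi, bj, bk = i, j, k
                if bi < 0:
                    break
                # move the outward cell into the hole
                phase[hx, hy, hz] = phase[bi, bj, bk]
                clock[hx, hy, hz] = clock[bi, bj, bk]
                scale[hx, hy, hz] = scale[bi, bj, bk]
                fate[hx, hy, hz] = fate[bi, bj, bk]
                delay[hx, hy, hz] = delay[bi, bj, bk]
                arrest[hx, hy, hz] = arrest[bi, bj, bk]
                hypoxic[hx, hy, hz] = hypoxic[bi, bj, bk]
                parity[hx, hy, hz] = parity[bi, bj, bk]
                _clear_voxel(phase, clock, scale, fate, delay, arrest, hypoxic, parity, bi, bj, bk)
                moved += 1
                hx, hy, hz = bi, bj, bk
        total += moved
        if moved == 0:
            return total
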