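"""Numba kernels: the per-step inner loops of the growth and walker models.

The kernels mirror the reference (pure-Python) engine in :mod:`.simulator`
exactly in model semantics — agents are processed sequentially in a freshly
shuffled order; each agent undergoes death → move → energy update →
duplication — but run orders of magnitude faster, which is what makes the
100-replicate ensembles tractable.  Each kernel seeds numba's internal RNG
from its ``seed`` argument, so runs are deterministic per (inputs, seed).

Grid codes: 0 = empty, 1 = pillar, 2 = bacterium.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: Moore neighbourhood, fixed order (the direction index is what the RNG draws).
_DR = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_DC = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)

# Duplication requires E_D to have reached 1; energies are float sums of the
# growth rate so the comparison uses a small tolerance (0.1 added ten times is
# 1 - 1e-16 in binary floating point).
_E_TOL = 1e-9


@njit(cache=True)
def _shuffle(idx):  # in-place Fisher-Yates
    for i in range(len(idx) - 1, 0, -1):
        j = np.random.randint(0, i + 1)
        tmp = idx[i]
        idx[i] = idx[j]
        idx[j] = tmp


@njit(cache=True)
def _init_agents(grid, n_initial, rr, cc):
    """Place n_initial agents on distinct uniform empty pixels; returns count."""
    h, w = grid.shape
    empties_r = np.empty(h * w, dtype=np.int64)
    empties_c = np.empty(h * w, dtype=np.int64)
    m = 0
    for r in range(h):
        for c in range(w):
            if grid[r, c] == 0:
                empties_r[m] = r
                empties_c[m] = c
                m += 1
    if n_initial > m:
        return -1
    # partial Fisher-Yates: draw n_initial distinct indices uniformly
    for k in range(n_initial):
        j = k + np.random.randint(0, m - k)
        tr = empties_r[k]; empties_r[k] = empties_r[j]; empties_r[j] = tr
        tc = empties_c[k]; empties_c[k] = empties_c[j]; empties_c[j] = tc
        rr[k] = empties_r[k]
        cc[k] = empties_c[k]
        grid[rr[k], cc[k]] = 2
    return n_initial


@njit(cache=True)
def run_growth_kernel(
    obstacle,
    periphery,
    growth_rate,
    death_probability,
    energy_cost,
    n_initial,
    t_max,
    seed,
    snap_times,
    stop_count,
):
    """Full growth simulation; returns per-step counts and snapshots.

    Returns (totals, withins, n_steps_run, snapshots) where totals/withins
    have length t_max+1 (index = time step; entries beyond an early stop are
    -1) and snapshots is an int8 array (len(snap_times), H, W) with grid
    codes (unvisited snapshot times stay all -1).
    """
    np.random.seed(seed)
    h, w = obstacle.shape
    grid = np.zeros((h, w), dtype=np.int8)
    for r in range(h):
        for c in range(w):
            if obstacle[r, c]:
                grid[r, c] = 1

    # worst case mid-step: every pre-step agent still has a slot (dead ones are
    # compacted only at step end) plus one daughter each
    cap = 2 * h * w
    rr = np.empty(cap, dtype=np.int64)
    cc = np.empty(cap, dtype=np.int64)
    en = np.zeros(cap, dtype=np.float64)
    alive = np.zeros(cap, dtype=np.bool_)

    n = _init_agents(grid, n_initial, rr, cc)
    if n < 0:
        return (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            -1,
            np.empty((0, h, w), dtype=np.int8),
        )
    for i in range(n):
        alive[i] = True

    totals = np.full(t_max + 1, -1, dtype=np.int64)
    withins = np.full(t_max + 1, -1, dtype=np.int64)
    snaps = np.full((len(snap_times), h, w), -1, dtype=np.int8)

    # t = 0 record
    wi = 0
    for i in range(n):
        if periphery[rr[i], cc[i]]:
            wi += 1
    totals[0] = n
    withins[0] = wi
    for k in range(len(snap_times)):
        if snap_times[k] == 0:
            snaps[k] = grid.copy()

    order = np.empty(cap, dtype=np.int64)
    t_run = 0
    for t in range(1, t_max + 1):
        for i in range(n):
            order[i] = i
        _shuffle(order[:n])
        n_total = n  # daughters appended beyond n act next step
        for oi in range(n):
            i = order[oi]
            r = rr[i]
            c = cc[i]
            # 1. death
            if death_probability > 0.0 and np.random.random() < death_probability:
                grid[r, c] = 0
                alive[i] = False
                continue
            # 2. movement: one uniformly chosen Moore neighbour, no resampling
            d = np.random.randint(0, 8)
            nr = r + _DR[d]
            nc = c + _DC[d]
            moved = False
            if 0 <= nr < h and 0 <= nc < w and grid[nr, nc] == 0:
                grid[r, c] = 0
                grid[nr, nc] = 2
                rr[i] = nr
                cc[i] = nc
                r = nr
                c = nc
                moved = True
            # 3. energy update
            e = en[i] + growth_rate
            if moved:
                e -= energy_cost
            if e < 0.0:
                e = 0.0
            if e > 1.0 - _E_TOL:
                e = 1.0
            en[i] = e
            # 4. duplication
            if e == 1.0:
                n_empty = 0
                choice_r = 0
                choice_c = 0
                # reservoir-sample a uniform empty neighbour
                for d2 in range(8):
                    er = r + _DR[d2]
                    ec = c + _DC[d2]
                    if 0 <= er < h and 0 <= ec < w and grid[er, ec] == 0:
                        n_empty += 1
                        if np.random.randint(0, n_empty) == 0:
                            choice_r = er
                            choice_c = ec
                if n_empty > 0:
                    j = n_total
                    n_total += 1
                    rr[j] = choice_r
                    cc[j] = choice_c
                    en[j] = 0.0
                    alive[j] = True
                    grid[choice_r, choice_c] = 2
                    en[i] = 0.0
        # compact (stable) — daughters included
        m = 0
        for i in range(n_total):
            if alive[i]:
                if m != i:
                    rr[m] = rr[i]
                    cc[m] = cc[i]
                    en[m] = en[i]
                alive[m] = True
                m += 1
        for i in range(m, n_total):
            alive[i] = False
        n = m
        wi = 0
        for i in range(n):
            if periphery[rr[i], cc[i]]:
                wi += 1
        totals[t] = n
        withins[t] = wi
        for k in range(len(snap_times)):
            if snap_times[k] == t:
                snaps[k] = grid.copy()
        t_run = t
        if stop_count > 0 and n >= stop_count:
            break
    return totals, withins, t_run, snaps


@njit(cache=True)
def run_walker_kernel(obstacle, periphery, horizon, seed):
    """Single movement-only walker (no death, duplication, or energy gating).

    Returns (start_row, start_col, d_tot, outside_steps): the position is
    classified against the periphery after each of the ``horizon`` steps; the
    initial position is not counted.
    """
    np.random.seed(seed)
    h, w = obstacle.shape
    # uniform empty start by rejection (empty fraction is ≥ 0.7 in practice)
    r = np.random.randint(0, h)
    c = np.random.randint(0, w)
    while obstacle[r, c]:
        r = np.random.randint(0, h)
        c = np.random.randint(0, w)
    r0 = r
    c0 = c
    d_tot = 0
    outside = 0
    for _ in range(horizon):
        d = np.random.randint(0, 8)
        nr = r + _DR[d]
        nc = c + _DC[d]
        if 0 <= nr < h and 0 <= nc < w and not obstacle[nr, nc]:
            r = nr
            c = nc
            d_tot += 1
        if not periphery[r, c]:
            outside += 1
    return r0, c0, d_tot, outside
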