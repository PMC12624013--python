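"""The agent-based growth model.

Each bacterium occupies one lattice pixel of a :class:`~pillarsim.arrangements.PillarLayout`
field and carries a duplication energy ``E_D`` in [0, 1].  Per global time
step, agents are processed sequentially in a freshly shuffled order; each
agent in turn

1. dies with probability ``death_probability`` (its pixel is freed),
2. attempts a move to one uniformly drawn Moore neighbour (the move happens
   only if that pixel is inside the field, not a pillar, and unoccupied; a
   blocked draw is *not* resampled),
3. gains ``growth_rate`` of energy, minus ``energy_cost`` if it just moved
   and energy consumption is enabled, clamped to [0, 1],
4. duplicates if ``E_D`` has reached 1 and an empty Moore neighbour exists:
   the daughter (``E_D = 0``) is placed on a uniformly drawn empty neighbour
   and the parent's ``E_D`` resets to 0.  With ``E_D = 1`` but no empty
   neighbour the energy stays parked at 1 and duplication is retried on
   later steps.

Two engines implement these semantics: a fast numba kernel (default; used
for ensembles) and a pure-Python reference engine whose per-agent operations
are exposed below for fine-grained testing.  Both are deterministic given
the seed, but their random streams differ, so traces match statistically,
not bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from .arrangements import (
    ArrangementSpec,
    ConfigurationError,
    PeripheryMask,
    PillarLayout,
    make_layout,
    periphery_mask,
)

__all__ = [
    "SimParams",
    "AgentState",
    "World",
    "SimulationTrace",
    "Ensemble",
    "init_population",
    "attempt_move",
    "update_energy",
    "attempt_duplicate",
    "step",
    "run_simulation",
    "run_replicates",
    "calibrate_energy_cost",
    "derive_seeds",
]

#: Moore neighbourhood in the fixed order the engines draw from.
MOORE = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if not (dr == 0 and dc == 0)
)
_MOORE_ORDER = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]

_E_TOL = 1e-9  # duplication threshold tolerance for float energy sums


@dataclass(frozen=True)
class SimParams:
    """Model rates and run controls.

    ``growth_rate`` (energy/step) and ``death_probability`` (per agent per
    step) follow the published settings 0.1 and 0.01; ``energy_cost`` is the
    energy removed per *successful* move while consumption is enabled.  Its
    default 0.09 sits at the replacement balance for freely moving agents
    (duplication interval 1/(g−c) equal to the expected lifetime 1/δ), the
    smallest cost that stalls growth in the open bulk field while leaving
    pillar-confined agents strongly super-critical; see
    :func:`calibrate_energy_cost` to re-derive it.  ``energy_consumption_enabled=False``
    forces the effective cost to zero.
    """

    growth_rate: float = 0.1
    death_probability: float = 0.01
    energy_cost: float = 0.09
    energy_consumption_enabled: bool = True
    n_initial: int = 100
    t_max: int = 400
    seed: int = 0
    snapshot_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.growth_rate <= 1:
            raise ConfigurationError("growth_rate must be in (0, 1]")
        if not 0 <= self.death_probability <= 1:
            raise ConfigurationError("death_probability must be in [0, 1]")
        if not 0 <= self.energy_cost <= 1:
            raise ConfigurationError("energy_cost must be in [0, 1]")
        if self.n_initial < 0:
            raise ConfigurationError("n_initial must be ≥ 0")
        if self.t_max < 0:
            raise ConfigurationError("t_max must be ≥ 0")

    @property
    def effective_cost(self) -> float:
        return self.energy_cost if self.energy_consumption_enabled else 0.0


@dataclass
class AgentState:
    """One bacterium: lattice position, duplication energy, move count."""

    row: int
    col: int
    energy: float = 0.0
    total_displacement: int = 0
    alive: bool = True

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class World:
    """Mutable state of the reference engine."""

    layout: PillarLayout
    periphery: PeripheryMask
    params: SimParams
    agents: list[AgentState]
    occupancy: np.ndarray  # bool grid: True where an agent sits
    t: int = 0

    @classmethod
    def create(cls, layout: PillarLayout, params: SimParams, rng: np.random.Generator) -> "World":
        peri = periphery_mask(layout)
        agents = init_population(layout, params, rng)
        occ = np.zeros_like(layout.obstacle_mask)
        for a in agents:
            occ[a.row, a.col] = True
        return cls(layout, peri, params, agents, occ)

    def counts(self) -> tuple[int, int, int]:
        within = sum(1 for a in self.agents if self.periphery.mask[a.row, a.col])
        total = len(self.agents)
        return total, within, total - within


@dataclass
class SimulationTrace:
    """Per-step population counts plus optional occupancy snapshots."""

    t: np.ndarray
    total: np.ndarray
    within_periphery: np.ndarray
    outside_periphery: np.ndarray
    snapshots: dict[int, np.ndarray]
    params: SimParams
    layout: PillarLayout

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "total": self.total,
                "within_periphery": self.within_periphery,
                "outside_periphery": self.outside_periphery,
            }
        )

    def count_at(self, t: int) -> int:
        idx = np.searchsorted(self.t, t)
        if idx >= len(self.t) or self.t[idx] != t:
            raise KeyError(f"step {t} not recorded (trace covers 0..{self.t[-1]})")
        return int(self.total[idx])

    def first_time_reaching(self, count: int) -> int | None:
        """First recorded step with total ≥ count, or None."""
        hits = np.nonzero(self.total >= count)[0]
        return int(self.t[hits[0]]) if len(hits) else None


# ---------------------------------------------------------------------------
# reference-engine operations
# ---------------------------------------------------------------------------


def init_population(
    layout: PillarLayout, params: SimParams, rng: np.random.Generator
) -> list[AgentState]:
    """``n_initial`` agents on distinct uniformly sampled empty pixels, E_D=0."""
    empty = np.argwhere(~layout.obstacle_mask)
    if params.n_initial > len(empty):
        raise ConfigurationError(
            f"n_initial={params.n_initial} exceeds the {len(empty)} empty pixels"
        )
    chosen = rng.choice(len(empty), size=params.n_initial, replace=False)
    return [AgentState(int(empty[i][0]), int(empty[i][1])) for i in chosen]


def attempt_move(
    agent: AgentState,
    occupancy: np.ndarray,
    layout: PillarLayout,
    rng: np.random.Generator,
) -> bool:
    """One uniformly drawn Moore neighbour; relocate iff it is free.

    The draw is not resampled on failure; walls and pillars block alike.
    """
    dr, dc = _MOORE_ORDER[rng.integers(0, 8)]
    nr, nc = agent.row + dr, agent.col + dc
    h, w = occupancy.shape
    if 0 <= nr < h and 0 <= nc < w and not layout.obstacle_mask[nr, nc] and not occupancy[nr, nc]:
        occupancy[agent.row, agent.col] = False
        occupancy[nr, nc] = True
        agent.row, agent.col = nr, nc
        agent.total_displacement += 1
        return True
    return False


def update_energy(agent: AgentState, moved: bool, params: SimParams) -> AgentState:
    """E_D ← clamp(E_D + g − c·[moved and consumption on], 0, 1)."""
    e = agent.energy + params.growth_rate
    if moved:
        e -= params.effective_cost
    e = min(max(e, 0.0), 1.0)
    if e > 1.0 - _E_TOL:
        e = 1.0
    agent.energy = e
    return agent


def attempt_duplicate(
    agent: AgentState,
    occupancy: np.ndarray,
    layout: PillarLayout,
    rng: np.random.Generator,
) -> AgentState | None:
    """Spawn a daughter on a uniform empty Moore neighbour iff E_D = 1.

    The daughter starts with E_D = 0 and zero displacement; the parent's E_D
    resets to 0.  With no empty neighbour the parent stays parked at E_D = 1.
    """
    if agent.energy < 1.0:
        return None
    h, w = occupancy.shape
    free = [
        (agent.row + dr, agent.col + dc)
        for dr, dc in _MOORE_ORDER
        if 0 <= agent.row + dr < h
        and 0 <= agent.col + dc < w
        and not layout.obstacle_mask[agent.row + dr, agent.col + dc]
        and not occupancy[agent.row + dr, agent.col + dc]
    ]
    if not free:
        return None
    nr, nc = free[rng.integers(0, len(free))]
    occupancy[nr, nc] = True
    agent.energy = 0.0
    return AgentState(nr, nc)


def step(world: World, params: SimParams, rng: np.random.Generator) -> World:
    """Advance the world one global time step (death → move → energy → duplicate)."""
    agents = world.agents
    order = rng.permutation(len(agents))
    newborn: list[AgentState] = []
    for i in order:
        a = agents[i]
        if params.death_probability > 0 and rng.random() < params.death_probability:
            world.occupancy[a.row, a.col] = False
            a.alive = False
            continue
        moved = attempt_move(a, world.occupancy, world.layout, rng)
        update_energy(a, moved, params)
        daughter = attempt_duplicate(a, world.occupancy, world.layout, rng)
        if daughter is not None:
            newborn.append(daughter)
    world.agents = [a for a in agents if a.alive] + newborn
    world.t += 1
    return world


def _run_reference(layout: PillarLayout, params: SimParams) -> SimulationTrace:
    rng = np.random.default_rng(params.seed)
    world = World.create(layout, params, rng)
    records = [world.counts()]
    snaps: dict[int, np.ndarray] = {}

    def _grid() -> np.ndarray:
        g = np.zeros(layout.obstacle_mask.shape, dtype=np.int8)
        g[layout.obstacle_mask] = 1
        g[world.occupancy] = 2
        return g

    if 0 in params.snapshot_times:
        snaps[0] = _grid()
    for t in range(1, params.t_max + 1):
        step(world, params, rng)
        records.append(world.counts())
        if t in params.snapshot_times:
            snaps[t] = _grid()
    total, within, outside = (np.array(v, dtype=np.int64) for v in zip(*records))
    return SimulationTrace(
        np.arange(params.t_max + 1), total, within, outside, snaps, params, layout
    )


# ---------------------------------------------------------------------------
# production runs
# ---------------------------------------------------------------------------


def run_simulation(
    layout: PillarLayout,
    params: SimParams,
    engine: str = "fast",
    stop_at_count: int | None = None,
) -> SimulationTrace:
    """Run one full simulation on ``layout``.

    ``engine="fast"`` uses the numba kernel; ``engine="reference"`` the
    pure-Python implementation (identical semantics, different random
    stream).  ``stop_at_count`` truncates the run once the population first
    reaches the given count (fast engine only; the trace then ends at that
    step instead of ``t_max``).
    """
    if params.n_initial > layout.empty_pixel_count:
        raise ConfigurationError(
            f"n_initial={params.n_initial} exceeds the {layout.empty_pixel_count} empty pixels"
        )
    if engine == "reference":
        if stop_at_count is not None:
            raise ConfigurationError("stop_at_count is only supported by the fast engine")
        return _run_reference(layout, params)
    if engine != "fast":
        raise ConfigurationError(f"unknown engine {engine!r}")

    peri = periphery_mask(layout)
    snap_times = np.asarray(sorted(set(params.snapshot_times)), dtype=np.int64)
    totals, withins, t_run, snaps = _kernels.run_growth_kernel(
        layout.obstacle_mask,
        peri.mask,
        params.growth_rate,
        params.death_probability,
        params.effective_cost,
        params.n_initial,
        params.t_max,
        params.seed,
        snap_times,
        0 if stop_at_count is None else int(stop_at_count),
    )
    if t_run < 0:
        raise ConfigurationError("n_initial exceeds the number of empty pixels")
    # population extinction or early stop leaves the tail unrecorded (-1)
    valid = totals >= 0
    n_rec = int(valid.sum())
    t_axis = np.arange(len(totals))[valid]
    totals = totals[valid]
    withins = withins[valid]
    snapshots = {
        int(st): snaps[k]
        for k, st in enumerate(snap_times)
        if st <= t_axis[-1] and (snaps[k] >= 0).all()
    }
    return SimulationTrace(
        t_axis, totals, withins, totals - withins, snapshots, params, layout
    )


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """n independent sub-seeds (< 2^31) from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n).astype(np.int64) & 0x7FFFFFFF


@dataclass
class Ensemble:
    """Replicate traces from one master seed, with boxplot-style summaries."""

    traces: list[SimulationTrace]

    def counts_at(self, t: int) -> np.ndarray:
        return np.array([tr.count_at(t) for tr in self.traces])

    def median_curve(self) -> pd.DataFrame:
        t = self.traces[0].t
        mat = np.stack([tr.total for tr in self.traces])
        q1, med, q3 = np.percentile(mat, [25, 50, 75], axis=0)
        return pd.DataFrame({"t": t, "median": med, "q1": q1, "q3": q3})

    def boxplot_stats(self, t: int) -> dict:
        x = self.counts_at(t)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        return {
            "t": t,
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(lo),
            "whisker_high": float(hi),
            "n": len(x),
        }

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for rep, tr in enumerate(self.traces):
            df = tr.to_dataframe()
            df.insert(0, "replicate", rep)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def run_replicates(
    layout: PillarLayout, params: SimParams, n_reps: int, engine: str = "fast"
) -> Ensemble:
    """``n_reps`` independent replicates with sub-seeds derived from params.seed."""
    if n_reps < 1:
        raise ConfigurationError("n_reps must be ≥ 1")
    seeds = derive_seeds(params.seed, n_reps)
    traces = [
        run_simulation(layout, replace(params, seed=int(s)), engine=engine) for s in seeds
    ]
    return Ensemble(traces)


def calibrate_energy_cost(
    layout_bulk: PillarLayout,
    params: SimParams,
    candidate_costs: list[float],
    n_reps: int = 10,
    t_window: tuple[int, int] = (50, 400),
) -> tuple[float, pd.DataFrame]:
    """Smallest candidate cost that stalls growth in the open (bulk) field.

    For each candidate, runs an ensemble with consumption enabled and fits a
    straight line to the median population count over ``t_window``; returns
    the smallest candidate whose slope is ≤ 0, together with the full slope
    table.  This encodes the observation that freely moving bacteria must be
    sub-replacement: with growth rate g, cost c and death probability δ, the
    replacement threshold is 1/(g−c) = 1/δ.
    """
    costs = sorted(candidate_costs)
    if not costs:
        raise ConfigurationError("no candidate costs given")
    if any(not 0 < c <= params.growth_rate for c in costs):
        raise ConfigurationError("candidate costs must lie in (0, growth_rate]")
    lo, hi = t_window
    if hi > params.t_max:
        raise ConfigurationError("t_window exceeds params.t_max")
    rows = []
    chosen = None
    for c in costs:
        p = replace(params, energy_cost=c, energy_consumption_enabled=True)
        ens = run_replicates(layout_bulk, p, n_reps)
        curve = ens.median_curve()
        sel = (curve["t"] >= lo) & (curve["t"] <= hi)
        slope = np.polyfit(curve["t"][sel], curve["median"][sel], 1)[0]
        rows.append({"energy_cost": c, "median_slope": float(slope)})
        if chosen is None and slope <= 0:
            chosen = c
    table = pd.DataFrame(rows)
    if chosen is None:
        raise ConfigurationError(
            f"no candidate cost stalls bulk growth; slopes:\n{table.to_string(index=False)}"
        )
    return chosen, table
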