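"""Growth-model semantics: movement, energy, duplication, death, ensembles."""

import itertools
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from pillarsim import ArrangementSpec, SimParams, make_layout
from pillarsim.arrangements import ConfigurationError
from pillarsim.simulator import (
    AgentState,
    World,
    attempt_duplicate,
    attempt_move,
    calibrate_energy_cost,
    derive_seeds,
    init_population,
    run_replicates,
    run_simulation,
    step,
    update_energy,
)
from conftest import make_custom_layout

MOORE = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@pytest.fixture(scope="module")
def small_bulk():
    return make_layout(ArrangementSpec("bulk", field_size=32))


class TestEnergy:
    @pytest.mark.parametrize(
        ("e0", "moved", "cost", "expected"),
        [
            (0.35, False, 0.095, 0.45),
            (0.0, True, 0.095, 0.005),
            (0.95, False, 0.095, 1.0),   # clamp at 1
            (0.05, True, 0.2, 0.0),      # would go negative without the clamp
        ],
    )
    def test_update_arithmetic(self, e0, moved, cost, expected):
        params = SimParams(energy_cost=cost)
        agent = AgentState(0, 0, energy=e0)
        update_energy(agent, moved, params)
        assert agent.energy == pytest.approx(expected, abs=1e-12)

    def test_stationary_agent_reaches_one_in_ten_steps(self):
        # closed form: ceil(1 / growth_rate) = 10 increments of 0.1
        params = SimParams()
        agent = AgentState(0, 0)
        for t in range(1, 11):
            update_energy(agent, False, params)
            if t < 10:
                assert agent.energy < 1.0
        assert agent.energy == 1.0


class TestInitPopulation:
    def test_distinct_positions_off_pillars(self, array_layout):
        rng = np.random.default_rng(0)
        agents = init_population(array_layout, SimParams(n_initial=100), rng)
        positions = {a.position for a in agents}
        assert len(positions) == 100
        assert all(not array_layout.obstacle_mask[a.row, a.col] for a in agents)
        assert all(a.energy == 0.0 for a in agents)

    def test_empty_population(self, bulk_layout):
        assert init_population(bulk_layout, SimParams(n_initial=0), np.random.default_rng(0)) == []

    def test_deterministic_under_seed(self, fractal_layout):
        p = SimParams(n_initial=50)
        a = init_population(fractal_layout, p, np.random.default_rng(7))
        b = init_population(fractal_layout, p, np.random.default_rng(7))
        assert [x.position for x in a] == [x.position for x in b]

    def test_overfull_raises(self):
        lay = make_layout(ArrangementSpec("bulk", field_size=13, pillar_radius=3))
        with pytest.raises(ConfigurationError):
            init_population(lay, SimParams(n_initial=170), np.random.default_rng(0))


class TestMovement:
    def test_fully_blocked_agent_never_moves(self):
        mask = np.ones((12, 12), dtype=bool)
        mask[5, 5] = False
        layout = make_custom_layout(mask)
        occ = np.zeros((12, 12), dtype=bool)
        occ[5, 5] = True
        agent = AgentState(5, 5)
        rng = np.random.default_rng(0)
        assert not any(attempt_move(agent, occ, layout, rng) for _ in range(200))
        assert agent.position == (5, 5)
        assert agent.total_displacement == 0

    def test_open_interior_always_moves(self, small_bulk):
        rng = np.random.default_rng(1)
        occ = np.zeros((32, 32), dtype=bool)
        agent = AgentState(16, 16)
        occ[16, 16] = True
        for _ in range(50):
            assert attempt_move(agent, occ, small_bulk, rng)
        assert agent.total_displacement == 50

    def test_direction_frequencies_uniform(self, small_bulk):
        # multinomial oracle: 80k draws, each direction 1/8 within 3 sigma
        rng = np.random.default_rng(2)
        occ = np.zeros((32, 32), dtype=bool)
        counts = Counter()
        n = 80_000
        for _ in range(n):
            agent = AgentState(16, 16)
            occ[:] = False
            occ[16, 16] = True
            attempt_move(agent, occ, small_bulk, rng)
            counts[(agent.row - 16, agent.col - 16)] += 1
        sigma = np.sqrt(n * (1 / 8) * (7 / 8))
        for d in MOORE:
            assert abs(counts[d] - n / 8) < 3 * sigma


class TestDuplication:
    def _enclosed(self):
        mask = np.ones((12, 12), dtype=bool)
        mask[5, 5] = False
        return make_custom_layout(mask)

    def test_blocked_duplication_keeps_energy(self):
        layout = self._enclosed()
        occ = np.zeros((12, 12), dtype=bool)
        occ[5, 5] = True
        agent = AgentState(5, 5, energy=1.0)
        assert attempt_duplicate(agent, occ, layout, np.random.default_rng(0)) is None
        assert agent.energy == 1.0

    def test_single_slot_duplication(self):
        mask = np.ones((12, 12), dtype=bool)
        mask[5, 5] = False
        mask[5, 6] = False
        layout = make_custom_layout(mask)
        occ = np.zeros((12, 12), dtype=bool)
        occ[5, 5] = True
        agent = AgentState(5, 5, energy=1.0)
        daughter = attempt_duplicate(agent, occ, layout, np.random.default_rng(0))
        assert daughter is not None
        assert daughter.position == (5, 6)
        assert daughter.energy == 0.0 and daughter.total_displacement == 0
        assert agent.energy == 0.0
        assert occ[5, 6]

    def test_below_threshold_never_duplicates(self, small_bulk):
        occ = np.zeros((32, 32), dtype=bool)
        occ[4, 4] = True
        agent = AgentState(4, 4, energy=0.999999999)
        assert attempt_duplicate(agent, occ, small_bulk, np.random.default_rng(0)) is None

    def test_population_first_doubles_at_ten_steps(self, small_bulk):
        # 1/g oracle: a lone agent with no death first duplicates at t = 10
        p = SimParams(
            death_probability=0.0, energy_consumption_enabled=False, n_initial=1, t_max=12, seed=5
        )
        tr = run_simulation(small_bulk, p, engine="reference")
        assert tr.total[9] == 1
        assert tr.total[10] == 2


class TestStep:
    def test_certain_death_extinguishes(self, small_bulk):
        for engine in ("fast", "reference"):
            p = SimParams(death_probability=1.0, n_initial=30, t_max=3, seed=1)
            tr = run_simulation(small_bulk, p, engine=engine)
            assert tr.total[0] == 30
            assert (tr.total[1:] == 0).all()

    def test_no_removal_means_nondecreasing(self, small_bulk):
        p = SimParams(
            death_probability=0.0, energy_consumption_enabled=False, n_initial=5, t_max=60, seed=3
        )
        tr = run_simulation(small_bulk, p, engine="reference")
        assert (np.diff(tr.total) >= 0).all()

    @pytest.mark.parametrize("engine", ["fast", "reference"])
    def test_same_seed_identical_trace(self, small_bulk, engine):
        p = SimParams(n_initial=20, t_max=40, seed=11)
        a = run_simulation(small_bulk, p, engine=engine)
        b = run_simulation(small_bulk, p, engine=engine)
        assert np.array_equal(a.total, b.total)
        assert np.array_equal(a.within_periphery, b.within_periphery)

    def test_occupancy_conservation_and_energy_bounds(self):
        layout = make_layout(ArrangementSpec("array", field_size=64))
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            params = SimParams(n_initial=40, seed=seed)
            world = World.create(layout, params, rng)
            for _ in range(50):
                step(world, params, rng)
                positions = [a.position for a in world.agents]
                assert len(positions) == len(set(positions))
                assert len(positions) == world.occupancy.sum()
                assert all(not layout.obstacle_mask[r, c] for r, c in positions)
                assert all(0.0 <= a.energy <= 1.0 for a in world.agents)

    def test_one_step_outcome_distribution_matches_enumeration(self, small_bulk):
        """Exhaustive oracle: every RNG path of one step, two adjacent agents.

        With no death and no consumption, both agents (E_D = 0.9) reach 1 and
        duplicate after their move.  The oracle enumerates processing order ×
        move directions × daughter placements with exact probabilities and is
        compared with 10,000 empirical steps of the reference engine.
        """
        start = [(5, 5), (5, 6)]

        def neighbours(pos):
            return [(pos[0] + dr, pos[1] + dc) for dr, dc in MOORE]

        def legal(pos, occupied):
            r, c = pos
            return 0 <= r < 32 and 0 <= c < 32 and pos not in occupied

        # --- exact enumeration (independent reimplementation of one step) ---
        exact = Counter()
        for order in itertools.permutations(range(2)):
            for dirs in itertools.product(range(8), repeat=2):
                # state: agent positions plus daughters
                pos = dict(enumerate(start))
                daughters = []
                weight = 0.5 * (1 / 8) ** 2
                outcomes = [(pos, daughters, weight)]
                for idx in order:
                    new_outcomes = []
                    for pos, daughters, weight in outcomes:
                        pos = dict(pos)
                        occupied = set(pos.values()) | set(daughters)
                        target = neighbours(pos[idx])[dirs[idx]]
                        if legal(target, occupied):
                            pos[idx] = target
                        # energy 0.9 + 0.1 -> 1.0: duplicate into uniform empty slot
                        occupied = set(pos.values()) | set(daughters)
                        slots = [q for q in neighbours(pos[idx]) if legal(q, occupied)]
                        for s in slots:
                            new_outcomes.append((pos, daughters + [s], weight / len(slots)))
                        if not slots:
                            new_outcomes.append((pos, daughters, weight))
                    outcomes = new_outcomes
                for pos, daughters, weight in outcomes:
                    exact[tuple(sorted(list(pos.values()) + daughters))] += weight
        assert sum(exact.values()) == pytest.approx(1.0)

        # --- empirical distribution from the engine ---
        n_trials = 10_000
        params = SimParams(death_probability=0.0, energy_consumption_enabled=False)
        empirical = Counter()
        for t in range(n_trials):
            rng = np.random.default_rng(10_000 + t)
            occ = np.zeros((32, 32), dtype=bool)
            agents = [AgentState(r, c, energy=0.9) for r, c in start]
            for a in agents:
                occ[a.row, a.col] = True
            world = World(small_bulk, None, params, agents, occ)
            world.periphery = type("P", (), {"mask": np.zeros((32, 32), dtype=bool)})()
            step(world, params, rng)
            empirical[tuple(sorted(a.position for a in world.agents))] += 1

        tv = 0.5 * sum(
            abs(exact[k] - empirical[k] / n_trials) for k in set(exact) | set(empirical)
        )
        # expected TV from multinomial noise alone is ≈ 0.4 × Σ√(p(1−p)/N);
        # allow 2.5× that mean
        noise = sum(np.sqrt(p * (1 - p) / n_trials) for p in exact.values())
        assert tv < noise
        # pointwise 5-sigma agreement on all non-rare outcomes
        for k, p in exact.items():
            if p >= 0.005:
                sigma = np.sqrt(p * (1 - p) / n_trials)
                assert abs(empirical[k] / n_trials - p) < 5 * sigma, k

    def test_engines_agree_statistically(self):
        layout = make_layout(ArrangementSpec("array", field_size=64))
        finals = {}
        for engine in ("fast", "reference"):
            finals[engine] = [
                run_simulation(
                    layout,
                    SimParams(energy_consumption_enabled=False, n_initial=10, t_max=25, seed=s),
                    engine=engine,
                ).total[-1]
                for s in range(40)
            ]
        assert stats.ks_2samp(finals["fast"], finals["reference"]).pvalue > 1e-3


class TestTraces:
    def test_partition_and_capacity(self, fractal_layout):
        p = SimParams(t_max=80, seed=2, snapshot_times=(0, 40))
        tr = run_simulation(fractal_layout, p)
        assert np.array_equal(tr.total, tr.within_periphery + tr.outside_periphery)
        assert (tr.total <= fractal_layout.empty_pixel_count).all()
        assert set(tr.snapshots) == {0, 40}
        snap = tr.snapshots[40]
        assert np.array_equal(snap == 1, fractal_layout.obstacle_mask)
        assert (snap == 2).sum() == tr.total[40]

    def test_zero_horizon(self, bulk_layout):
        tr = run_simulation(bulk_layout, SimParams(t_max=0, seed=0))
        assert list(tr.t) == [0]
        assert tr.total[0] == 100


class TestEnsembles:
    def test_single_replicate_equals_trace(self, small_bulk):
        p = SimParams(n_initial=10, t_max=30, seed=9)
        ens = run_replicates(small_bulk, p, 1)
        solo = run_simulation(small_bulk, replace(p, seed=int(derive_seeds(9, 1)[0])))
        assert np.array_equal(ens.traces[0].total, solo.total)

    def test_median_matches_direct_recomputation(self, small_bulk):
        p = SimParams(n_initial=10, t_max=30, seed=4)
        ens = run_replicates(small_bulk, p, 7)
        direct = np.median([tr.count_at(30) for tr in ens.traces])
        assert ens.boxplot_stats(30)["median"] == direct
        assert np.median(ens.counts_at(30)) == direct

    def test_same_master_seed_identical(self, small_bulk):
        p = SimParams(n_initial=10, t_max=20, seed=123)
        a = run_replicates(small_bulk, p, 4)
        b = run_replicates(small_bulk, p, 4)
        for ta, tb in zip(a.traces, b.traces):
            assert np.array_equal(ta.total, tb.total)


class TestCalibration:
    def test_selects_smallest_stalling_cost(self):
        bulk = make_layout(ArrangementSpec("bulk", field_size=64))
        p = SimParams(n_initial=30, t_max=150, seed=1)
        chosen, table = calibrate_energy_cost(
            bulk, p, [0.02, 0.1], n_reps=4, t_window=(50, 150)
        )
        assert chosen == 0.1
        slopes = dict(zip(table["energy_cost"], table["median_slope"]))
        assert slopes[0.02] > 0       # near-free movement reduces to unchecked growth
        assert slopes[0.1] <= 0       # cost equal to the growth rate blocks duplication

    def test_failure_reports_slopes(self):
        bulk = make_layout(ArrangementSpec("bulk", field_size=64))
        p = SimParams(n_initial=30, t_max=120, seed=1)
        with pytest.raises(ConfigurationError, match="slope"):
            calibrate_energy_cost(bulk, p, [0.01], n_reps=3, t_window=(40, 120))

    def test_candidate_domain_validated(self, small_bulk):
        with pytest.raises(ConfigurationError):
            calibrate_energy_cost(small_bulk, SimParams(), [0.5])
        with pytest.raises(ConfigurationError):
            calibrate_energy_cost(small_bulk, SimParams(), [])
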