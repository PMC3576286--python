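"""Cellular-automata engine: feeding draws, per-cycle rules, determinism."""

import numpy as np
import pytest
from scipy.stats import norm

from degensim import automata as ca
from degensim.trait_space import ConfigurationError, rectangular_resource


@pytest.fixture()
def small_world(grid300):
    return rectangular_resource(grid300, 0, 299, 10.0)


def default_params(**kw):
    kw.setdefault("sigma", 0.0)
    return ca.CAParams(**kw)


class TestBoxMuller:
    def test_moments_of_large_sample(self, rng):
        z = ca.box_muller(rng, 10**5)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1.0) < 0.01

    def test_odd_request_length(self, rng):
        assert len(ca.box_muller(rng, 7)) == 7


class TestDrawFeedLocation:
    def test_sigma_zero_feeds_in_place(self, rng):
        for _ in range(10):
            assert ca.draw_feed_location(42, 0.0, rng, n_points=300) == 42

    def test_draw_moments(self, rng):
        draws = np.array([ca.draw_feed_location(150, 60.0, rng) for _ in range(10**5)])
        assert abs(draws.mean() - 150.0) < 1.0
        assert abs(draws.std() - 60.0) < 2.0

    def test_edge_location_misses_about_half(self, rng):
        # sigma=120 at location 0: lower tail below 0 is lost; CDF oracle
        n = 10**5
        misses = sum(
            ca.draw_feed_location(0, 120.0, rng, n_points=300) == ca.OUT_OF_RANGE
            for _ in range(n)
        )
        oracle = norm.cdf(-0.5 / 120.0) + (1 - norm.cdf(299.5 / 120.0))
        assert misses / n == pytest.approx(oracle, abs=0.01)
        assert misses / n == pytest.approx(0.5, abs=0.015)


class TestStepAutomaton:
    def test_energy_recursion_sets_first_reproduction_cycle(self, grid300, small_world):
        # lone automaton, abundant resource, sigma=0: e <- e - 0.5 + 1, from 1.
        # Independent iteration of that recursion crosses the threshold 5 on
        # cycle 9 (e = 5.5), so the first REPRODUCED event occurs there.
        params = default_params(maintenance_fraction=0.5, consume_unit=1.0,
                                initial_energy=1.0, repro_threshold=5.0)
        e, cycle = 1.0, 0
        while True:
            cycle += 1
            e = e - 0.5 + 1.0
            if e > 5.0:
                break
        assert (cycle, e) == (9, 5.5)

        state = ca.init_state(grid300, small_world, [(150, 1)], params, seed=0)
        a = ca.Automaton(150, params.initial_energy)
        events = []
        for _ in range(cycle):
            state.remaining = small_world.capacity.copy()
            events.append(ca.step_automaton(a, state, params)[0])
        assert events[:-1] == [ca.SURVIVED] * (cycle - 1)
        assert events[-1] == ca.REPRODUCED

    def test_starvation_kills(self, grid300):
        # no resource anywhere: maintenance alone grinds energy to <= 0
        empty = rectangular_resource(grid300, 0, 0, 1.0)
        state = ca.init_state(grid300, empty, [(299, 1)], default_params(), seed=0)
        state.remaining = np.zeros(300)
        a = ca.Automaton(299, 1.0)
        events = set()
        for _ in range(10):
            events.add(ca.step_automaton(a, state, default_params())[0])
            if ca.DIED in events:
                break
        assert ca.DIED in events

    def test_out_of_range_draw_skips_consumption(self, grid300, small_world):
        params = default_params(sigma=1000.0)  # nearly every draw misses
        state = ca.init_state(grid300, small_world, [(150, 1)], params, seed=0)
        a = ca.Automaton(150, 3.0)
        before = state.remaining.sum()
        misses = 0
        for _ in range(20):
            a.energy = 3.0
            ca.step_automaton(a, state, params)
            if a.energy < 3.0:  # maintenance only, no feed
                misses += 1
        assert misses > 0
        assert state.remaining.sum() >= before - 20 * params.consume_unit

    def test_reproduction_deducts_child_energy(self, grid300, small_world):
        params = default_params()
        state = ca.init_state(grid300, small_world, [(150, 1)], params, seed=0)
        a = ca.Automaton(150, 6.0)
        event, child = ca.step_automaton(a, state, params)
        assert event == ca.REPRODUCED
        assert child.location == 150 and child.energy == params.initial_energy
        assert a.energy == pytest.approx(6.0 - 0.5 + 1.0 - params.initial_energy)


class TestSpawnOffspring:
    def test_zero_mutability_copies_parent(self, rng):
        assert ca.spawn_offspring(150, default_params(mutability=0.0), rng, 300) == 150

    def test_mutability_sets_dispersion(self, rng):
        params = default_params(mutability=2.0)
        kids = np.array([ca.spawn_offspring(150, params, rng, 300) for _ in range(10**5)])
        assert abs(kids.std() - 2.0) < 0.15

    def test_children_clipped_to_grid(self, rng):
        params = default_params(mutability=2.0)
        kids = [ca.spawn_offspring(0, params, rng, 300) for _ in range(2000)]
        assert min(kids) >= 0


class TestRunCycle:
    def test_empty_population_only_ticks_clock(self, grid300, small_world):
        state = ca.init_state(grid300, small_world, [], default_params(), seed=0)
        out = ca.run_cycle(state, default_params())
        assert out.cycle == 1 and out.population_size == 0

    def test_resource_conservation_per_cycle(self, grid300, small_world):
        params = default_params(sigma=30.0)
        state = ca.init_state(grid300, small_world, [(i, 2) for i in range(0, 300, 3)], params, seed=2)
        for _ in range(20):
            e_before = state.energies.sum()
            n_before = state.population_size
            ca.run_cycle(state, params)
            consumed = np.sum(state.base_resource.capacity - state.remaining)
            assert consumed == state.consumed_last_cycle
            assert consumed <= state.base_resource.capacity.sum()
            # energy bookkeeping: gains = consumption, losses = maintenance,
            # deaths and newborn transfers cancel within the population
            assert np.all(state.energies > 0)

    def test_exclusion_at_a_single_unit_cell(self, grid300):
        point = rectangular_resource(grid300, 150, 150, 1.0)
        params = default_params(consume_unit=1.0, maintenance_fraction=0.5,
                                initial_energy=1.0, repro_threshold=5.0)
        state = ca.init_state(grid300, point, [(150, 2)], params, seed=0)
        ca.run_cycle(state, params)
        # exactly one automaton got the single unit
        assert state.consumed_last_cycle == 1.0
        fed = np.isclose(state.energies, 1.0 - 0.5 + 1.0)
        unfed = np.isclose(state.energies, 1.0 - 0.5)
        assert fed.sum() == 1 and unfed.sum() == 1

    def test_children_do_not_act_in_birth_cycle(self, grid300):
        # parent reproduces onto a cell holding one unit: the newborn must not
        # feed (or be processed at all) until the next cycle
        point = rectangular_resource(grid300, 150, 150, 1.0)
        params = default_params()
        state = ca.init_state(grid300, point, [(150, 1)], params, seed=0)
        state.energies[:] = 6.0
        ca.run_cycle(state, params)
        assert state.population_size == 2
        assert state.consumed_last_cycle == 1.0  # parent's feed only

    def test_no_dead_automata_cross_cycle_boundaries(self, grid300, small_world):
        params = default_params(sigma=60.0, death_prob=0.02)
        state = ca.init_state(grid300, small_world, [(i, 1) for i in range(300)], params, seed=3)
        for _ in range(50):
            ca.run_cycle(state, params)
            assert np.all(state.energies > 0)

    def test_sequential_and_vectorized_paths_are_bit_identical(self, grid300, small_world):
        params = default_params(sigma=30.0, mutability=2.0, death_prob=0.01)
        s_vec = ca.init_state(grid300, small_world, [(150, 20)], params, seed=7)
        s_seq = ca.init_state(grid300, small_world, [(150, 20)], params, seed=7)
        for _ in range(60):
            ca.run_cycle(s_vec, params, sequential=False)
            ca.run_cycle(s_seq, params, sequential=True)
        assert np.array_equal(s_vec.locations, s_seq.locations)
        assert np.array_equal(s_vec.energies, s_seq.energies)
        assert np.array_equal(s_vec.remaining, s_seq.remaining)

    def test_population_guard_trips(self, grid300, small_world):
        params = default_params(max_population=5)
        state = ca.init_state(grid300, small_world, [(150, 10)], params, seed=0)
        with pytest.raises(RuntimeError):
            ca.run_cycle(state, params)


class TestRun:
    def test_seed_determinism(self, grid300, small_world):
        params = default_params(sigma=60.0, mutability=2.0)
        out = []
        for _ in range(2):
            state = ca.init_state(grid300, small_world, [(150, 5)], params, seed=11)
            ts = ca.run(state, params, n_cycles=200, snapshot_every=50)
            out.append(np.stack([s.mass for s in ts.snapshots]))
        assert np.array_equal(out[0], out[1])

    def test_empty_start_reports_extinct(self, grid300, small_world):
        params = default_params()
        state = ca.init_state(grid300, small_world, [], params, seed=0)
        ts = ca.run(state, params, n_cycles=10)
        assert ts.status == "extinct"

    def test_single_founder_start(self, grid300, small_world):
        params = default_params(sigma=60.0)
        state = ca.init_state(grid300, small_world, [(150, 1)], params, seed=0)
        assert state.population_size == 1 and state.locations[0] == 150

    def test_founder_outside_grid_rejected(self, grid300, small_world):
        with pytest.raises(ConfigurationError):
            ca.init_state(grid300, small_world, [(500, 1)], default_params(), seed=0)
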