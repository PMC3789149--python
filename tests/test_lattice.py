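"""Lattice contact process: initialization, trials, stepping, measurements."""

import numpy as np
import pytest

from phytolattice import (BracketFailureError, Community, ConfigurationError,
                          LatticeState, SimConfig, SpeciesParams,
                          adjacency_stats, birth_trial, death_trial,
                          default_community, estimate_threshold, init_lattice,
                          mc_step, richness, run_simulation,
                          run_single_species)


def single_species_community(mortality=0.3):
    return Community((SpeciesParams(1, 0.9, 1.0, mortality=mortality),))


class TestInitLattice:
    def test_exact_counts_and_even_split(self):
        cfg = SimConfig(P=14.0, L=100, steps=0, seed=5, initial_occupancy=0.3)
        state = init_lattice(cfg, default_community(10))
        counts = state.counts(10)
        assert counts[1:].sum() == 3000
        assert np.all(counts[1:] == 300)

    def test_full_lattice_single_species(self):
        cfg = SimConfig(P=14.0, L=20, steps=0, seed=5, initial_occupancy=1.0)
        state = init_lattice(cfg, single_species_community())
        assert np.all(state.grid == 1)

    def test_deterministic_given_seed(self, community10):
        cfg = SimConfig(P=14.0, L=50, steps=0, seed=42)
        a = init_lattice(cfg, community10)
        b = init_lattice(cfg, community10)
        assert np.array_equal(a.grid, b.grid)

    def test_occupancy_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(P=14.0, L=50, initial_occupancy=1.5)


class TestSingleTrials:
    def test_death_trial_noop_at_zero_mortality(self, rng):
        c = Community((SpeciesParams(1, 0.9, 1.0, mortality=0.0),))
        state = LatticeState(np.ones((10, 10), dtype=np.int8))
        for _ in range(200):
            death_trial(state, c, rng)
        assert np.all(state.grid == 1)

    def test_death_trial_certain_at_unit_mortality(self, rng):
        c = Community((SpeciesParams(1, 0.9, 1.0, mortality=1.0),))
        state = LatticeState(np.ones((5, 5), dtype=np.int8))
        death_trial(state, c, rng)
        assert state.grid.sum() == 24  # exactly the chosen cell emptied

    def test_death_trial_ignores_empty_cells(self, rng):
        c = single_species_community(mortality=1.0)
        state = LatticeState(np.zeros((5, 5), dtype=np.int8))
        death_trial(state, c, rng)
        assert np.all(state.grid == 0)

    @pytest.mark.parametrize("mode", ["local", "global"])
    def test_birth_trial_noop_on_empty_and_full(self, mode, rng):
        c = single_species_community()
        empty = LatticeState(np.zeros((6, 6), dtype=np.int8))
        full = LatticeState(np.ones((6, 6), dtype=np.int8))
        for _ in range(100):
            birth_trial(empty, c, mode, 15.0, rng)
            birth_trial(full, c, mode, 15.0, rng)
        assert np.all(empty.grid == 0) and np.all(full.grid == 1)

    def test_local_birth_lands_on_von_neumann_neighbor(self, rng):
        """Every new individual appears orthogonally adjacent to an existing
        one, so the colony grows as one connected cluster."""
        c = single_species_community()
        grid = np.zeros((9, 9), dtype=np.int8)
        grid[4, 4] = 1
        state = LatticeState(grid)
        occupied = {(4, 4)}
        for _ in range(300):
            birth_trial(state, c, "local", 25.0, rng)  # b ~ b_max there
            now = set(zip(*map(tuple, np.nonzero(state.grid))))
            new = now - occupied
            assert len(new) <= 1
            for (i, j) in new:
                assert any((int(i) - pi) % 9 in (1, 8) and j == pj
                           or (int(j) - pj) % 9 in (1, 8) and i == pi
                           for pi, pj in occupied)
            occupied = now
        assert len(occupied) >= 2  # births did occur


class TestMcStep:
    def test_survival_fraction_matches_uniform_trial_oracle(self, rng):
        """Full lattice, certain death, no births: after one sweep of L*L
        uniform death trials each cell persists with probability
        (1 - 1/L**2)**(L**2) ~ 1/e."""
        L = 50
        c = single_species_community(mortality=1.0)
        cfg = SimConfig(P=0.0, L=L, steps=1, seed=0, record_every=0)
        expected = (1.0 - 1.0 / L**2) ** (L**2)
        fracs = []
        for _ in range(200):
            state = LatticeState(np.ones((L, L), dtype=np.int8))
            mc_step(state, c, cfg, rng)
            fracs.append(state.grid.sum() / L**2)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.005)

    def test_mortality_thinning_matches_escape_probability(self, rng):
        """With births off, one step thins occupancy by ~exp(-m)."""
        L, m = 50, 0.3
        c = Community((SpeciesParams(1, 0.9, 1.0, b0=1e-6, mortality=m),))
        cfg = SimConfig(P=0.0, L=L, steps=1, seed=0, record_every=0)
        fracs = []
        for _ in range(200):
            state = LatticeState(np.ones((L, L), dtype=np.int8))
            mc_step(state, c, cfg, rng)  # b(P=0) = 1e-6, effectively off
            fracs.append(state.grid.sum() / L**2)
        expected = (1.0 - m / L**2) ** (L**2)
        assert np.mean(fracs) == pytest.approx(expected, abs=0.005)

    def test_no_removal_when_mortality_zero(self, rng):
        c = Community((SpeciesParams(1, 0.9, 1.0, mortality=0.0),))
        cfg = SimConfig(P=15.0, L=30, steps=1, seed=0, record_every=0)
        state = init_lattice(cfg, c)
        prev = state.grid.sum()
        for _ in range(5):
            mc_step(state, c, cfg, rng)
            assert state.grid.sum() >= prev
            prev = state.grid.sum()


class TestRunSimulation:
    def test_zero_steps_yields_initial_record(self, tiny_cfg, community10):
        cfg = SimConfig(P=14.5, L=40, steps=0, seed=1)
        series, state = run_simulation(cfg, community10)
        assert len(series.steps) == 1 and series.steps[0] == 0
        np.testing.assert_array_equal(series.densities[0],
                                      state.densities(community10.n))

    def test_bit_identical_given_seed(self, tiny_cfg, community10):
        s1, st1 = run_simulation(tiny_cfg, community10)
        s2, st2 = run_simulation(tiny_cfg, community10)
        assert np.array_equal(s1.densities, s2.densities)
        assert np.array_equal(st1.grid, st2.grid)

    def test_conservation_and_cell_values(self, tiny_cfg, community10):
        series, state = run_simulation(tiny_cfg, community10)
        np.testing.assert_array_equal(
            series.empty + series.densities.sum(axis=1),
            np.ones(len(series.steps)))
        assert set(np.unique(state.grid)) <= set(range(community10.n + 1))

    def test_subthreshold_single_species_goes_extinct(self):
        """Below the local extinction threshold the population dies out."""
        dens = run_single_species(0.45, 0.3, "local", L=100, steps=2000, seed=3)
        assert dens == 0.0


class TestRichness:
    def test_counts_extant_species(self):
        empty = LatticeState(np.zeros((8, 8), dtype=np.int8))
        assert richness(empty) == 0
        grid = np.zeros((8, 8), dtype=np.int8)
        grid[0, 0], grid[5, 5] = 2, 7
        assert richness(LatticeState(grid)) == 2
        assert richness(LatticeState(np.ones((8, 8), dtype=np.int8))) == 1

    def test_accepts_density_vector(self):
        assert richness(np.array([0.0, 0.2, 0.0, 0.01])) == 2


class TestAdjacencyStats:
    def test_empty_lattice(self):
        st = adjacency_stats(LatticeState(np.zeros((10, 10), dtype=np.int8)))
        assert st.empty_empty_pairs == 200
        assert st.total == 200

    def test_two_species_checkerboard(self):
        L = 8
        grid = np.fromfunction(lambda i, j: 1 + (i + j) % 2, (L, L)).astype(np.int8)
        st = adjacency_stats(LatticeState(grid))
        assert st.cross_species_pairs == 2 * L * L
        assert st.same_species_pairs == 0

    def test_full_single_species(self):
        st = adjacency_stats(LatticeState(np.ones((9, 9), dtype=np.int8)))
        assert st.same_species_pairs == 2 * 81

    def test_total_invariant_on_random_grid(self, rng):
        grid = rng.integers(0, 4, size=(13, 13)).astype(np.int8)
        st = adjacency_stats(LatticeState(grid))
        assert st.total == 2 * 13 * 13


class TestEstimateThreshold:
    def test_zero_mortality_persists_at_grid_minimum(self):
        grid = [0.2, 0.3, 0.4]
        est = estimate_threshold("local", 0.0, 30, 50, grid, 3, seed=1)
        assert est == grid[0]

    def test_bracket_failure_when_nothing_persists(self):
        with pytest.raises(BracketFailureError):
            estimate_threshold("local", 1.0, 30, 200, [0.02, 0.05], 3, seed=1)

    def test_grid_must_be_ascending(self):
        with pytest.raises(ValueError):
            estimate_threshold("local", 0.3, 30, 50, [0.5, 0.4], 3, seed=1)
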