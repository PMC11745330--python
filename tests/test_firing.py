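"""T6SS firing, hit resolution, intoxication, and lysis tests."""

import numpy as np
import pytest

from t6sim.cells import Population, build_grid
from t6sim.firing import (FiringRates, cull_and_lyse, intoxicate, resolve_hits,
                          sample_firing_counts, spawn_needles,
                          spawn_needles_population)
from t6sim.fixtures import make_fixture
from t6sim.geometry import needle_entry_parameter, point_segment_closest


def crowd(rng, n=50, span=8.0):
    pop = Population(n_toxins=1)
    pop.add_cells([0] * n, rng.uniform(-span, span, (n, 2)),
                  rng.uniform(0, 2 * np.pi, n), rng.uniform(0.5, 2.5, n))
    return pop


def brute_force_hits(firer_idx, base, direction, pop):
    """All-pairs first-intersection oracle, no spatial grid."""
    p1, p2 = pop.endpoints
    out = []
    for k in range(firer_idx.size):
        best_t, best_j = np.inf, -1
        for j in range(len(pop)):
            if j == firer_idx[k]:
                continue
            t = needle_entry_parameter(base[k][None], direction[k][None],
                                       p1[j][None], p2[j][None],
                                       pop.radius, pop.radius)[0]
            if t < best_t:
                best_t, best_j = t, j
        if np.isfinite(best_t):
            out.append((k, best_j, best_t))
    return out


class TestFiringCounts:
    def test_zero_rate_means_zero_counts(self, rng):
        pop = crowd(rng, 10)
        counts = sample_firing_counts(pop, np.ones(10, bool), 0.0, 0.5, rng)
        assert not counts.any()

    def test_dead_cells_never_fire(self, rng):
        pop = crowd(rng, 10)
        pop.alive[:5] = False
        counts = sample_firing_counts(pop, np.ones(10, bool), 50.0, 1.0, rng)
        assert not counts[:5].any()
        assert counts[5:].any()

    def test_poisson_mean_over_many_draws(self, rng):
        n = 100_000
        pop = Population(n_toxins=1)
        pop.add_cells([0] * n, np.zeros((n, 2)), np.zeros(n), np.ones(n))
        counts = sample_firing_counts(pop, np.ones(n, bool), 4.0, 0.5, rng)
        mean, target = counts.mean(), 2.0
        se = np.sqrt(target / n)
        assert abs(mean - target) < 3 * se

    def test_realised_rate_matches_k_fire_over_long_run(self, rng):
        pop = crowd(rng, 50)
        k_fire, dt, steps = 3.0, 0.025, 400
        total = sum(sample_firing_counts(pop, np.ones(50, bool), k_fire, dt, rng).sum()
                    for _ in range(steps))
        hours = 50 * dt * steps
        se = np.sqrt(k_fire / hours)
        assert abs(total / hours - k_fire) < 3 * se


class TestSpawnNeedles:
    def test_zero_needles(self, rng):
        pop = crowd(rng, 3)
        assert spawn_needles(pop.cell(0), 0, rng) == []

    def test_bases_lie_on_the_membrane(self, rng):
        pop = crowd(rng, 5)
        p1, p2 = pop.endpoints
        idx, base, direction = spawn_needles_population(
            pop, np.full(5, 40), rng)
        _, dist = point_segment_closest(base, p1[idx], p2[idx])
        np.testing.assert_allclose(dist, pop.radius, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(direction, axis=1), 1.0, atol=1e-12)

    def test_outward_direction_in_uniform_mode(self, rng):
        pop = crowd(rng, 5)
        idx, base, direction = spawn_needles_population(
            pop, np.full(5, 40), rng, direction_mode="uniform")
        p1, p2 = pop.endpoints
        closest, _ = point_segment_closest(base, p1[idx], p2[idx])
        outward = base - closest
        outward /= np.linalg.norm(outward, axis=1, keepdims=True)
        assert (np.einsum("ij,ij->i", outward, direction) > -1e-9).all()

    def test_fixed_seed_reproduces_needle_set(self):
        pop = crowd(np.random.default_rng(3), 5)
        a = spawn_needles_population(pop, np.full(5, 7), np.random.default_rng(9))
        b = spawn_needles_population(pop, np.full(5, 7), np.random.default_rng(9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestResolveHits:
    def test_aimed_needle_strikes_expected_target(self):
        pop, ndl = make_fixture("aimed-needle")
        grid = build_grid(pop)
        nk, tk, dist = resolve_hits(ndl["firer_idx"], ndl["base"],
                                    ndl["direction"], pop, grid)
        assert tk.tolist() == [1]
        assert dist[0] == pytest.approx(ndl["expected_entry"])

    def test_isolated_needle_misses(self):
        pop = Population(n_toxins=1)
        pop.add_cells([0, 0], [[0.0, 0.0], [0.0, 5.0]], [0.0, 0.0], [1.0, 1.0])
        grid = build_grid(pop)
        nk, tk, _ = resolve_hits(np.array([0]), np.array([[0.0, 0.5]]),
                                 np.array([[0.0, 1.0]]), pop, grid)
        assert nk.size == 0

    def test_only_nearer_of_stacked_cells_is_hit(self):
        pop = Population(n_toxins=1)
        # two horizontal rods stacked above the firer along the needle path
        pop.add_cells([0, 1, 1], [[0.0, 0.0], [0.0, 1.3], [0.0, 2.2]],
                      [0.0] * 3, [1.0] * 3)
        grid = build_grid(pop)
        nk, tk, dist = resolve_hits(np.array([0]), np.array([[0.0, 0.5]]),
                                    np.array([[0.0, 1.0]]), pop, grid)
        assert tk.tolist() == [1]

    def test_matches_all_pairs_oracle_on_random_population(self, rng):
        pop = crowd(rng, 50)
        counts = rng.poisson(2.0, 50)
        idx, base, direction = spawn_needles_population(pop, counts, rng)
        grid = build_grid(pop)
        nk, tk, dist = resolve_hits(idx, base, direction, pop, grid)
        expected = brute_force_hits(idx, base, direction, pop)
        got = list(zip(nk.tolist(), tk.tolist()))
        assert got == [(k, j) for k, j, _ in expected]
        np.testing.assert_allclose(dist, [t for _, _, t in expected], atol=1e-12)

    def test_never_hits_own_firer_and_distance_bounded(self, rng):
        pop = crowd(rng, 40, span=4.0)
        counts = rng.poisson(3.0, 40)
        idx, base, direction = spawn_needles_population(pop, counts, rng)
        nk, tk, dist = resolve_hits(idx, base, direction, pop, build_grid(pop))
        assert (idx[nk] != tk).all()
        assert (dist <= pop.radius + 1e-12).all()


class TestIntoxication:
    def setup_pair(self, sens, n_toxins=2, same_strain=False):
        pop = Population(n_toxins=n_toxins)
        pop.add_cells([0, 0 if same_strain else 1],
                      [[0.0, 0.0], [0.0, 1.3]], [0.0, 0.0], [1.0, 1.0])
        arsenal = np.zeros((2, n_toxins))
        sensitivity = np.zeros((2, n_toxins))
        sensitivity[1] = sens
        return pop, arsenal, sensitivity

    def test_single_toxin_hit_kills_fully_sensitive_target(self):
        pop, arsenal, sens = self.setup_pair([1.0, 1.0])
        arsenal[0] = [1.0, 0.0]
        n = intoxicate(np.array([0]), np.array([1]), pop, arsenal, sens, None, now=2.0)
        assert n == 1
        assert not pop.alive[1]
        assert pop.death_time[1] == 2.0
        assert pop.growth_rate[1] == 0.0

    def test_two_toxin_hit_adds_unit_of_each(self):
        pop, arsenal, sens = self.setup_pair([0.3, 0.3])
        arsenal[0] = [1.0, 1.0]
        intoxicate(np.array([0]), np.array([1]), pop, arsenal, sens, None, now=1.0)
        np.testing.assert_array_equal(pop.toxins[1], [1.0, 1.0])
        assert pop.alive[1]

    def test_clonemates_are_immune(self):
        pop, arsenal, sens = self.setup_pair([1.0, 1.0], same_strain=True)
        arsenal[0] = [1.0, 1.0]
        n = intoxicate(np.array([0]), np.array([0 + 1]), pop, arsenal, sens, None, now=1.0)
        assert n == 0
        assert pop.alive.all()
        assert not pop.toxins.any()

    def test_corpses_absorb_overkill_without_state_change(self):
        pop, arsenal, sens = self.setup_pair([1.0, 1.0])
        arsenal[0] = [1.0, 0.0]
        intoxicate(np.array([0]), np.array([1]), pop, arsenal, sens, None, now=1.0)
        intoxicate(np.array([0]), np.array([1]), pop, arsenal, sens, None, now=2.0)
        assert pop.toxins[1, 0] == 2.0
        assert pop.death_time[1] == 1.0  # first death time sticks

    def test_interaction_matrix_respected(self):
        pop, arsenal, sens = self.setup_pair([0.3, 0.3])
        arsenal[0] = [1.0, 1.0]
        B = np.array([[0.0, 0.25], [0.25, 0.0]])
        n = intoxicate(np.array([0]), np.array([1]), pop, arsenal, sens, B, now=1.0)
        # I = 1 - 0.6 - 0.5 < 0: synergy kills where additivity would not
        assert n == 1


class TestLysis:
    def make_pop_with_corpse(self, death_time):
        pop = Population(n_toxins=1)
        pop.add_cells([0, 0], [[0.0, 0.0], [3.0, 0.0]], [0.0, 0.0], [1.0, 1.0])
        pop.alive[1] = False
        pop.death_time[1] = death_time
        return pop

    def test_corpse_removed_after_delay(self):
        pop = self.make_pop_with_corpse(death_time=1.0)
        removed = cull_and_lyse(pop, now=1.6, k_lysis=2.0)  # delay 0.5 h
        assert removed == 1 and len(pop) == 1 and pop.alive.all()

    def test_fresh_corpse_and_living_cells_retained(self):
        pop = self.make_pop_with_corpse(death_time=1.0)
        removed = cull_and_lyse(pop, now=1.2, k_lysis=2.0)
        assert removed == 0 and len(pop) == 2

    def test_short_delay_limit_removes_next_step(self):
        pop = self.make_pop_with_corpse(death_time=1.0)
        removed = cull_and_lyse(pop, now=1.0 + 1e-9, k_lysis=1e9)
        assert removed == 1

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            cull_and_lyse(self.make_pop_with_corpse(1.0), 2.0, 0.0)
        with pytest.raises(ValueError):
            FiringRates(k_fire=-1.0, k_lysis=2.0)
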