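"""Competition assembly, summary statistics, and invariants."""

import math

import numpy as np
import pandas as pd
import pytest

from t6sim.competition import (CompetitionConfig, StrainSpec, absolute_fitness,
                               competitive_advantage,
                               mean_competitive_advantage, protection_sweep,
                               run_competition, run_replicates, seed_disc,
                               rng_for_replicate)
from t6sim.firing import FiringRates


def small_config(**kw):
    defaults = dict(
        strains=(
            StrainSpec("attacker", 40, sensitivity=[0.0, 0.0], arsenal=[1.0, 0.0]),
            StrainSpec("susceptible", 12, sensitivity=[1.0, 1.0]),
            StrainSpec("mutant", 4, sensitivity=[0.0, 1.0]),
        ),
        arena_radius=15.0, duration=1.0, dt=0.05,
        rates=FiringRates(2.0, 2.0), seed=5)
    defaults.update(kw)
    return CompetitionConfig(**defaults)


class TestCompetitiveAdvantage:
    @pytest.mark.parametrize("initial, final, expected", [
        ((10, 90), (20, 90), 2.0),
        ((10, 90), (30, 270), 1.0),
        ((10, 90), (0, 50), 0.0),
        ((10, 90), (5, 0), math.inf),
    ])
    def test_ratio_of_ratios_and_degenerate_conventions(self, initial, final, expected):
        assert competitive_advantage(initial, final) == expected

    def test_joint_extinction_is_undefined(self):
        assert math.isnan(competitive_advantage((10, 90), (0, 0)))

    def test_zero_initial_counts_rejected(self):
        with pytest.raises(ValueError):
            competitive_advantage((0, 90), (1, 1))

    def test_label_swap_inverts_advantage(self):
        ca = competitive_advantage((10, 90), (25, 60))
        inv = competitive_advantage((90, 10), (60, 25))
        assert ca == pytest.approx(1.0 / inv)


class TestAbsoluteFitness:
    @pytest.mark.parametrize("n0, n1, t0, t1, expected", [
        (10, 20, 0.0, 1.0, 1.0),
        (10, 80, 0.0, 2.0, 1.5),
        (10, 10, 0.0, 5.0, 0.0),
    ])
    def test_division_rate(self, n0, n1, t0, t1, expected):
        assert absolute_fitness(n0, n1, t0, t1) == pytest.approx(expected)

    def test_extinction_reports_negative_infinity(self):
        assert absolute_fitness(10, 0, 0.0, 1.0) == -math.inf

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            absolute_fitness(0, 5, 0.0, 1.0)
        with pytest.raises(ValueError):
            absolute_fitness(5, 5, 1.0, 1.0)


class TestSeeding:
    def test_counts_and_radius(self):
        cfg = small_config()
        pop = seed_disc(cfg, rng_for_replicate(0, 0))
        assert len(pop) == 56
        counts = pop.alive_counts(3)
        assert counts.tolist() == [40, 12, 4]
        # relaxation may nudge cells slightly past the nominal radius
        assert np.linalg.norm(pop.pos, axis=1).max() <= cfg.arena_radius + 2.0

    def test_same_seed_identical_layout(self):
        cfg = small_config()
        a = seed_disc(cfg, rng_for_replicate(3, 1))
        b = seed_disc(cfg, rng_for_replicate(3, 1))
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.angle, b.angle)

    def test_infeasible_packing_rejected(self):
        cfg = small_config(
            strains=(StrainSpec("s", 500, sensitivity=[1.0, 1.0]),),
            arena_radius=5.0)
        with pytest.raises(ValueError, match="infeasible"):
            seed_disc(cfg, rng_for_replicate(0, 0))


class TestRunCompetition:
    def test_bit_identical_replay(self):
        cfg = small_config()
        a = run_competition(cfg, replicate=2)
        b = run_competition(cfg, replicate=2)
        pd.testing.assert_frame_equal(a.counts_over_time, b.counts_over_time)
        assert a.final_counts == b.final_counts

    def test_population_bookkeeping_identity(self):
        """Cells born = alive + dead-unlysed + lysed, per strain."""
        cfg = small_config(duration=2.0)
        res = run_competition(cfg, replicate=0, keep_population=True)
        pop = res.final_population
        for s in range(3):
            alive = int((pop.alive & (pop.strain == s)).sum())
            dead_unlysed = int(((~pop.alive) & (pop.strain == s)).sum())
            lysed = pop.lysed_per_strain.get(s, 0)
            assert pop.born_per_strain.get(s, 0) == alive + dead_unlysed + lysed

    def test_neutral_labels_mean_advantage_near_one(self):
        """Two identical strains without attackers drift around CA = 1."""
        cfg = CompetitionConfig(
            strains=(StrainSpec("mutant", 15, sensitivity=[1.0]),
                     StrainSpec("susceptible", 15, sensitivity=[1.0])),
            arena_radius=12.0, duration=2.0, dt=0.05,
            rates=FiringRates(0.0, 2.0), seed=17, replicates=24)
        results = run_replicates(cfg)
        cas = np.array([r.competitive_advantage("mutant", "susceptible")
                        for r in results])
        assert np.isfinite(cas).all()
        se = cas.std(ddof=1) / np.sqrt(cas.size)
        assert abs(cas.mean() - 1.0) <= max(3 * se, 0.05)

    def test_resistant_mutant_selected_by_matching_attacker(self):
        """The scaled selection scenario: immune mutant gains advantage."""
        cfg = small_config(duration=3.0, rates=FiringRates(1.0, 2.0))
        results = run_replicates(cfg, 6)
        mean_ca = mean_competitive_advantage(results, "mutant", "susceptible")
        assert mean_ca > 1.0

    def test_extra_toxin_never_helps_the_target(self):
        """Mean target survival under a two-toxin dose is no higher than
        under the single-toxin dose at matched parameters."""
        def final_targets(arsenal, seed):
            cfg = CompetitionConfig(
                strains=(StrainSpec("attacker", 40, sensitivity=[0.0, 0.0],
                                    arsenal=arsenal),
                         StrainSpec("target", 15, sensitivity=[0.6, 0.6])),
                arena_radius=14.0, duration=2.0, dt=0.05,
                rates=FiringRates(3.0, 2.0), seed=seed)
            return [run_competition(cfg, r).final_counts["target"] for r in range(6)]

        single = np.mean(final_targets([1.0, 0.0], seed=23))
        double = np.mean(final_targets([1.0, 1.0], seed=23))
        assert double <= single

    def test_all_target_extinction_recorded_not_raised(self):
        cfg = small_config(
            strains=(StrainSpec("attacker", 50, sensitivity=[0.0, 0.0],
                                arsenal=[1.0, 0.0]),
                     StrainSpec("susceptible", 2, sensitivity=[1.0, 1.0]),
                     StrainSpec("mutant", 2, sensitivity=[1.0, 1.0])),
            arena_radius=8.0, duration=6.0, rates=FiringRates(30.0, 2.0))
        res = run_competition(cfg, replicate=1)
        if res.all_targets_extinct:  # overwhelming attack, expected
            assert res.extinct["susceptible"] and res.extinct["mutant"]
            assert math.isnan(res.competitive_advantage("mutant", "susceptible"))
            # early termination: fewer steps recorded than the full horizon
            assert res.times[-1] <= cfg.duration + 1e-9


class TestProtectionSweep:
    def test_zero_attackers_show_no_protection_signal(self):
        table = protection_sweep([0], [16], [0.5], replicates=4,
                                 duration=1.5, arena_radius=12.0, seed=3)
        assert set(table["condition"]) == {"resistant", "control"}
        assert not table["cross_protected"].any()
        res = table[table.condition == "resistant"]["susceptible_fitness"]
        ctl = table[table.condition == "control"]["susceptible_fitness"]
        assert abs(res.mean() - ctl.mean()) < 0.2

    def test_resistance_gain_benefits_the_mutant_under_attack(self):
        table = protection_sweep([60], [16], [0.5], replicates=4,
                                 duration=2.0, arena_radius=12.0,
                                 rates=FiringRates(4.0, 2.0), seed=3)
        res = table[table.condition == "resistant"]["mutant_fitness"]
        ctl = table[table.condition == "control"]["mutant_fitness"]
        ctl = ctl[np.isfinite(ctl)]
        assert res.mean() > (ctl.mean() if len(ctl) else -1.0)

    def test_tidy_schema_one_row_per_condition_replicate(self):
        table = protection_sweep([0], [10], [0.5], replicates=3,
                                 duration=1.0, arena_radius=10.0, seed=1)
        assert len(table) == 6
        assert {"grid_id", "condition", "replicate", "mutant_fitness",
                "susceptible_fitness", "cross_protected"} <= set(table.columns)
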