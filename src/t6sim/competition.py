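"""Head-to-head T6SS competitions and their summary statistics.

A competition seeds a random mixture of attacker and target strains inside
a disc, then iterates the timestep loop

    grow -> divide -> relax overlaps -> fire -> resolve hits ->
    intoxicate -> cull/lyse

recording per-strain living counts at every step.  Summaries follow the
standard competition-assay statistics: the Competitive advantage of a rare
mutant relative to the more common susceptible strain,

    CA = (N_mut / N_sus)_final / (N_mut / N_sus)_initial,

and absolute (Malthusian) fitness in divisions per hour,

    fitness = log2(N_final / N_start) / (t_final - t_initial).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import cells as _cells
from .cells import Population, build_grid, relax_overlaps
from .firing import (FiringRates, cull_and_lyse, intoxicate, resolve_hits,
                     sample_firing_counts, spawn_needles_population)
from .toxins import growth_multiplier

DEFAULT_ARENA_RADIUS = 50.0  # um
DEFAULT_DURATION = 10.0      # h
DEFAULT_DT = 0.025           # h
DEFAULT_REPLICATES = 20
# defaults calibrated in-repo so that the qualitative single- vs multi-toxin
# selection structure is reproduced at desk scale; both are ordinary config
# fields
DEFAULT_K_FIRE = 1.0         # firings cell^-1 h^-1
DEFAULT_K_LYSIS = 2.0        # h^-1


@dataclass(frozen=True)
class StrainSpec:
    """One competing strain: label, phenotype, and initial abundance."""

    label: str
    count: int
    sensitivity: np.ndarray          # a_i per toxin; attackers typically all-zero
    arsenal: np.ndarray | None = None  # d_i per toxin; None for non-attackers
    growth_rate: float = _cells.DEFAULT_GROWTH_RATE

    def __post_init__(self):
        object.__setattr__(self, "sensitivity", np.atleast_1d(np.asarray(self.sensitivity, dtype=float)))
        if self.arsenal is not None:
            object.__setattr__(self, "arsenal", np.atleast_1d(np.asarray(self.arsenal, dtype=float)))
        if self.count < 0:
            raise ValueError(f"strain {self.label!r}: count must be >= 0")
        if np.any(self.sensitivity < 0) or np.any(self.sensitivity > 1):
            raise ValueError(f"strain {self.label!r}: sensitivities must lie in [0, 1]")
        if self.arsenal is not None and np.any(self.arsenal < 0):
            raise ValueError(f"strain {self.label!r}: doses must be >= 0")

    @property
    def is_attacker(self) -> bool:
        return self.arsenal is not None and bool(np.any(self.arsenal > 0))


@dataclass(frozen=True)
class CompetitionConfig:
    """Full parameterisation of one replicated competition experiment."""

    strains: tuple[StrainSpec, ...]
    arena_radius: float = DEFAULT_ARENA_RADIUS
    duration: float = DEFAULT_DURATION
    dt: float = DEFAULT_DT
    rates: FiringRates = field(default_factory=lambda: FiringRates(DEFAULT_K_FIRE, DEFAULT_K_LYSIS))
    B: np.ndarray | None = None
    cost_coefficient: float = 0.0
    seed: int = 0
    replicates: int = DEFAULT_REPLICATES
    relax_tolerance: float = 0.02
    relax_max_iterations: int = 100
    direction_mode: str = "normal"

    def __post_init__(self):
        object.__setattr__(self, "strains", tuple(self.strains))
        if not self.strains:
            raise ValueError("at least one strain is required")
        if self.duration <= 0 or self.dt <= 0:
            raise ValueError("duration and dt must be > 0")
        if self.cost_coefficient < 0:
            raise ValueError("cost_coefficient must be >= 0")
        n_tox = self.strains[0].sensitivity.size
        for s in self.strains:
            if s.sensitivity.size != n_tox or (s.arsenal is not None and s.arsenal.size != n_tox):
                raise ValueError("all strains must share the same toxin count")
        if self.B is not None:
            B = np.asarray(self.B, dtype=float)
            if B.shape != (n_tox, n_tox):
                raise ValueError(f"B must be {n_tox}x{n_tox}")
            object.__setattr__(self, "B", B)

    @property
    def n_toxins(self) -> int:
        return self.strains[0].sensitivity.size

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strains]

    def strain_index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class CompetitionResult:
    """Outcome of one competition replicate."""

    config: CompetitionConfig
    replicate: int
    times: np.ndarray
    counts_over_time: pd.DataFrame       # one row per step, one column per strain
    initial_counts: dict[str, int]
    final_counts: dict[str, int]
    extinct: dict[str, bool]
    all_targets_extinct: bool
    final_population: Population | None = None

    def competitive_advantage(self, mutant: str, susceptible: str) -> float:
        return competitive_advantage(
            (self.initial_counts[mutant], self.initial_counts[susceptible]),
            (self.final_counts[mutant], self.final_counts[susceptible]))

    def absolute_fitness(self, label: str) -> float:
        return absolute_fitness(self.initial_counts[label], self.final_counts[label],
                                float(self.times[0]), float(self.times[-1]))


def rng_for_replicate(seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate stream, independent of run scheduling."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(replicate)]))


def seed_disc(config: CompetitionConfig, rng: np.random.Generator) -> Population:
    """Place all strains uniformly at random inside the arena disc.

    Positions and orientations are uniform; initial volumes are drawn
    uniformly between one and two birth volumes so the population starts
    desynchronised.  A single overlap relaxation makes the layout
    mechanically consistent before the clock starts.
    """
    pop = Population(n_toxins=config.n_toxins)
    total_demand = 0.0
    for s_idx, s in enumerate(config.strains):
        n = s.count
        if n == 0:
            continue
        r = config.arena_radius * np.sqrt(rng.random(n))
        th = rng.uniform(0.0, 2.0 * np.pi, n)
        pos = np.stack([r * np.cos(th), r * np.sin(th)], axis=-1)
        angle = rng.uniform(0.0, 2.0 * np.pi, n)
        V0 = _cells.DEFAULT_BIRTH_VOLUME
        V = rng.uniform(V0, 2.0 * V0, n)
        length = _cells.length_from_volume(V)
        total_demand += float(np.sum(_cells.volume_from_length(length)))
        pop.add_cells(s_idx, pos, angle, length, growth_rate=s.growth_rate,
                      birth_volume=V0, rng=rng)
    disc_area = np.pi * config.arena_radius**2
    if total_demand > disc_area:
        raise ValueError(
            f"infeasible packing: cells demand {total_demand:.0f} um^2 "
            f"but the disc offers {disc_area:.0f} um^2")
    relax_overlaps(pop, config.relax_tolerance, config.relax_max_iterations)
    return pop


def run_competition(config: CompetitionConfig, replicate: int = 0,
                    keep_population: bool = False) -> CompetitionResult:
    """Run one replicate of the timestep loop to completion.

    The loop terminates early once every non-attacker strain has no living
    cells; that outcome is recorded, not raised.

    In confluent colonies the bounded per-step relaxation routinely ends at
    its iteration cap with a small, stable residual overlap (the numerical
    signature of compressive stress in a packed colony), so the solver's
    per-step saturation warnings are suppressed here; direct calls to
    :func:`t6sim.cells.relax_overlaps` still warn.
    """
    rng = rng_for_replicate(config.seed, replicate)
    pop = seed_disc(config, rng)
    n_strains = len(config.strains)
    attacker_strains = np.array([s.is_attacker for s in config.strains])
    arsenal = np.zeros((n_strains, config.n_toxins))
    sens = np.zeros((n_strains, config.n_toxins))
    growth_mult = np.ones(n_strains)
    for k, s in enumerate(config.strains):
        sens[k] = s.sensitivity
        if s.arsenal is not None:
            arsenal[k] = s.arsenal
        growth_mult[k] = growth_multiplier(s.sensitivity, config.cost_coefficient)

    n_steps = int(round(config.duration / config.dt))
    times = [0.0]
    counts = [pop.alive_counts(n_strains)]
    initial = counts[0].copy()

    for step in range(1, n_steps + 1):
        now = step * config.dt
        pop.grow(config.dt, growth_mult)
        pop.divide(rng)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="overlap relaxation")
            relax_overlaps(pop, config.relax_tolerance, config.relax_max_iterations)
        attacker_mask = attacker_strains[pop.strain]
        fire_counts = sample_firing_counts(pop, attacker_mask, config.rates.k_fire,
                                           config.dt, rng)
        if fire_counts.sum() > 0:
            firer_idx, base, direction = spawn_needles_population(
                pop, fire_counts, rng, config.direction_mode)
            grid = build_grid(pop)
            nk, tk, _ = resolve_hits(firer_idx, base, direction, pop, grid)
            intoxicate(firer_idx[nk], tk, pop, arsenal, sens, config.B, now)
        cull_and_lyse(pop, now, config.rates.k_lysis)
        pop.t = now
        times.append(now)
        counts.append(pop.alive_counts(n_strains))
        if counts[-1][~attacker_strains].sum() == 0:
            break

    final = counts[-1]
    labels = config.labels
    result = CompetitionResult(
        config=config, replicate=replicate,
        times=np.asarray(times),
        counts_over_time=pd.DataFrame(np.asarray(counts), columns=labels),
        initial_counts={l: int(c) for l, c in zip(labels, initial)},
        final_counts={l: int(c) for l, c in zip(labels, final)},
        extinct={l: bool(c == 0) for l, c in zip(labels, final)},
        all_targets_extinct=bool(final[~attacker_strains].sum() == 0),
        final_population=pop if keep_population else None,
    )
    return result


def run_replicates(config: CompetitionConfig, replicates: int | None = None,
                   keep_population: bool = False) -> list[CompetitionResult]:
    n = config.replicates if replicates is None else replicates
    return [run_competition(config, r, keep_population) for r in range(n)]


def competitive_advantage(initial_counts, final_counts) -> float:
    """Final mutant:susceptible ratio divided by its initial value.

    ``initial_counts`` and ``final_counts`` are ``(mutant, susceptible)``
    pairs.  Degenerate outcomes are encoded explicitly: mutant extinction
    gives 0, susceptible-only extinction gives +inf, and joint extinction
    gives NaN (undefined), so callers can average over defined replicates.
    """
    m0, s0 = initial_counts
    m1, s1 = final_counts
    if m0 <= 0 or s0 <= 0:
        raise ValueError("initial mutant and susceptible counts must be > 0")
    if m1 == 0 and s1 == 0:
        return math.nan
    if m1 == 0:
        return 0.0
    if s1 == 0:
        return math.inf
    return (m1 / s1) / (m0 / s0)


def absolute_fitness(n_start: float, n_final: float,
                     t_initial: float, t_final: float) -> float:
    """Realised division rate log2(N_final / N_start) / elapsed time."""
    if n_start <= 0:
        raise ValueError("n_start must be > 0")
    if t_final <= t_initial:
        raise ValueError("t_final must exceed t_initial")
    if n_final == 0:
        return -math.inf
    return math.log2(n_final / n_start) / (t_final - t_initial)


def mean_competitive_advantage(results: list[CompetitionResult], mutant: str,
                               susceptible: str, log_transform: bool = False) -> float:
    """Average CA over replicates where both focal strains survived."""
    values = []
    for res in results:
        ca = res.competitive_advantage(mutant, susceptible)
        if math.isfinite(ca) and ca > 0:
            values.append(math.log(ca) if log_transform else ca)
    if not values:
        return math.nan
    mean = float(np.mean(values))
    return math.exp(mean) if log_transform else mean


def protection_sweep(attacker_counts, target_counts, mutant_fractions,
                     cost_coefficients=(0.0,), replicates: int = 5,
                     duration: float = 3.0, arena_radius: float = 25.0,
                     dt: float = DEFAULT_DT, rates: FiringRates | None = None,
                     seed: int = 0, alpha: float = 0.05) -> pd.DataFrame:
    """Cross-protection parameter sweep for a single-toxin attacker.

    For every grid point, target cells split into a susceptible strain
    (``a_A = 1``) and a mutant strain that is either fully resistant
    (``a_A = 0``; treatment) or itself fully susceptible (control).
    Absolute fitness of both strains is recorded per replicate, and
    cross-protection is flagged when the susceptible strain's mean fitness
    is significantly higher alongside the resistant mutant than in the
    control (one-sided two-sample t-test at level ``alpha``).

    Returns a tidy frame with one row per (grid point, condition,
    replicate) plus per-grid-point significance columns.
    """
    rates = rates or FiringRates(DEFAULT_K_FIRE, DEFAULT_K_LYSIS)
    rows = []
    grid_id = 0
    for na in np.atleast_1d(attacker_counts):
        for nt in np.atleast_1d(target_counts):
            for mf in np.atleast_1d(mutant_fractions):
                for cost in np.atleast_1d(cost_coefficients):
                    nm = max(1, int(round(mf * nt)))
                    ns = max(1, int(nt) - nm)
                    fitness = {}
                    for cond_id, (condition, a_mut) in enumerate((("resistant", 0.0), ("control", 1.0))):
                        strains = (
                            StrainSpec("attacker", int(na), sensitivity=[0.0], arsenal=[1.0]),
                            StrainSpec("susceptible", ns, sensitivity=[1.0]),
                            StrainSpec("mutant", nm, sensitivity=[a_mut]),
                        )
                        cfg = CompetitionConfig(
                            strains=strains, arena_radius=arena_radius,
                            duration=duration, dt=dt, rates=rates,
                            cost_coefficient=cost,
                            seed=int(np.random.SeedSequence([seed, grid_id, cond_id]).generate_state(1)[0] % 2**31),
                            replicates=replicates)
                        res = run_replicates(cfg)
                        fitness[condition] = {
                            "mutant": [r.absolute_fitness("mutant") for r in res],
                            "susceptible": [r.absolute_fitness("susceptible") for r in res],
                        }
                    sus_res = np.asarray(fitness["resistant"]["susceptible"])
                    sus_ctl = np.asarray(fitness["control"]["susceptible"])
                    finite = np.isfinite(sus_res) & np.isfinite(sus_ctl)
                    if finite.sum() >= 2 and np.std(sus_res[finite]) > 0 and np.std(sus_ctl[finite]) > 0:
                        t_stat, p_two = stats.ttest_ind(sus_res[finite], sus_ctl[finite], equal_var=False)
                        p_one = p_two / 2.0 if t_stat > 0 else 1.0 - p_two / 2.0
                    else:
                        p_one = math.nan
                    cross_protected = bool(p_one < alpha) if math.isfinite(p_one) else False
                    for condition in ("resistant", "control"):
                        for rep in range(replicates):
                            rows.append({
                                "grid_id": grid_id, "n_attacker": int(na),
                                "n_target": int(nt), "mutant_fraction": float(mf),
                                "cost_coefficient": float(cost),
                                "condition": condition, "replicate": rep,
                                "mutant_fitness": fitness[condition]["mutant"][rep],
                                "susceptible_fitness": fitness[condition]["susceptible"][rep],
                                "cross_protection_p": p_one,
                                "cross_protected": cross_protected,
                            })
                    grid_id += 1
    return pd.DataFrame(rows)
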