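"""Adaptive-walk trajectories of T6SS resistance evolution.

The trajectory loop iterates mutate -> select -> replace: a rare mutant is
generated by perturbing the resident's per-toxin sensitivities with
independent Normal(0, sigma^2) draws (whole vectors leaving [0, 1] are
redrawn), the resident and mutant are subjected to T6SS selection by a
fixed attacker, and the mutant replaces the resident if it wins.

Two selection backends are provided:

* ``abm`` -- a spatially explicit tripartite competition (attacker :
  resident : mutant seeded 500:90:10 by default, 1.5 h).  The mutant fixes
  when its competitive advantage over the resident exceeds 1; stochastic
  advantages let near-neutral mutants drift to fixation.  Elimination of
  all target cells terminates the trajectory as an extinction.
* ``simplified`` -- an analytic fixation rule: the mutant fixes iff its
  phenotypic resistance strictly exceeds the resident's,
  ``Delta = N_hits(mutant) - N_hits(resident) > 0``.  Extinction cannot
  occur and drift is absent, so the fixation barrier is higher.  With a
  nonzero interaction matrix the additive closed form is invalid and
  hits-to-death is computed by direct dosing instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .competition import (CompetitionConfig, FiringRates, StrainSpec,
                          run_competition, DEFAULT_K_FIRE, DEFAULT_K_LYSIS)
from .toxins import growth_multiplier, hits_to_death, n_hits

DEFAULT_SIGMA = 0.1
DEFAULT_MAX_STEPS = 30
ABM_SEED_COUNTS = (500, 90, 10)   # attacker : resident : mutant
ABM_DURATION = 1.5                # h


class Outcome(str, Enum):
    FIXED = "FIXED"
    REJECTED = "REJECTED"
    EXTINCT = "EXTINCT"


@dataclass(frozen=True)
class MutationSpec:
    """Per-toxin Gaussian perturbation of sensitivities."""

    sigma: float = DEFAULT_SIGMA
    max_redraws: int = 10_000

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class AbmSelectionConfig:
    """Parameters of the agent-based selection competition.

    Defaults follow the trajectory protocol (500:90:10 seeding, 1.5 h);
    scaled-down counts and arenas are accepted for desk-size runs.
    """

    counts: tuple[int, int, int] = ABM_SEED_COUNTS
    duration: float = ABM_DURATION
    arena_radius: float = 50.0
    dt: float = 0.025
    rates: FiringRates = field(default_factory=lambda: FiringRates(DEFAULT_K_FIRE, DEFAULT_K_LYSIS))
    B: np.ndarray | None = None
    cost_coefficient: float = 0.0


@dataclass
class TrajectoryRecord:
    """One adaptive walk: visited resident states and per-step outcomes."""

    states: list[np.ndarray]
    outcomes: list[Outcome]
    terminated_by: str                 # "completed" | "extinction"
    attacker: np.ndarray
    endpoint_n_hits: float = math.nan

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-step table (step 0 is the starting state)."""
        rows = []
        for step, state in enumerate(self.states):
            row = {"step": step,
                   "outcome": "START" if step == 0 else self.outcomes[step - 1].value}
            row.update({f"a_{i + 1}": float(v) for i, v in enumerate(state)})
            row["n_hits"] = n_hits(state, self.attacker)
            rows.append(row)
        return pd.DataFrame(rows)


def propose_mutation(a: np.ndarray, spec: MutationSpec,
                     rng: np.random.Generator) -> np.ndarray:
    """Perturb every sensitivity by Normal(0, sigma^2); redraw if out of range.

    The whole vector is redrawn whenever any component leaves [0, 1], so
    accepted perturbations are draws from the truncated joint distribution.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if spec.sigma == 0:
        return a.copy()
    for _ in range(spec.max_redraws):
        candidate = a + rng.normal(0.0, spec.sigma, a.size)
        if np.all((candidate >= 0.0) & (candidate <= 1.0)):
            return candidate
    raise RuntimeError(
        f"no in-range mutation found in {spec.max_redraws} redraws (sigma={spec.sigma})")


def simplified_selection_step(resident, mutant, d, B=None,
                              cost_coefficient: float = 0.0,
                              hit_rate: float = 1.0,
                              growth_rate: float = np.log(2.0) / 2.5) -> Outcome:
    """Fix the mutant iff its phenotypic resistance strictly increases.

    With a nonzero interaction matrix the additive closed form is invalid,
    so hits-to-death is computed by direct repeated dosing.

    With a nonzero resistance cost, fixation compares a net-fitness score
    instead: each phenotype is scored as its (cost-discounted) growth rate
    minus an intoxication death rate ``hit_rate / N_hits``, the hazard a
    cell sustaining ``N_hits`` translocations faces when hits arrive at
    ``hit_rate`` per hour.  At zero cost the score comparison reduces
    exactly to the resistance comparison ``Delta > 0``.
    """
    def resistance(a):
        if B is not None and np.any(np.asarray(B)):
            return hits_to_death(a, d, B)
        return n_hits(a, d)

    if cost_coefficient == 0.0:
        delta = resistance(mutant) - resistance(resident)
        return Outcome.FIXED if delta > 0 else Outcome.REJECTED

    def score(a):
        death_rate = 0.0 if math.isinf(resistance(a)) else hit_rate / resistance(a)
        return growth_rate * growth_multiplier(a, cost_coefficient) - death_rate

    return Outcome.FIXED if score(mutant) > score(resident) else Outcome.REJECTED


def abm_selection_step(resident, mutant, attacker_arsenal,
                       config: AbmSelectionConfig, seed: int) -> Outcome:
    """Tripartite spatial competition deciding one trajectory step.

    FIXED when the mutant's competitive advantage over the resident
    strictly exceeds 1 (exactly-neutral outcomes are rejected; drift acts
    only through stochastic advantages), EXTINCT when no target cell of
    either strain survives, REJECTED otherwise.
    """
    attacker_arsenal = np.atleast_1d(np.asarray(attacker_arsenal, dtype=float))
    n_att, n_res, n_mut = config.counts
    strains = (
        StrainSpec("attacker", n_att, sensitivity=np.zeros_like(attacker_arsenal),
                   arsenal=attacker_arsenal),
        StrainSpec("resident", n_res, sensitivity=np.asarray(resident, dtype=float)),
        StrainSpec("mutant", n_mut, sensitivity=np.asarray(mutant, dtype=float)),
    )
    cfg = CompetitionConfig(
        strains=strains, arena_radius=config.arena_radius,
        duration=config.duration, dt=config.dt, rates=config.rates,
        B=config.B, cost_coefficient=config.cost_coefficient,
        seed=seed, replicates=1)
    res = run_competition(cfg, replicate=0)
    if res.all_targets_extinct:
        return Outcome.EXTINCT
    ca = res.competitive_advantage("mutant", "resident")
    if math.isnan(ca):
        return Outcome.EXTINCT
    return Outcome.FIXED if ca > 1.0 else Outcome.REJECTED


def run_trajectory(backend: str, attacker, spec: MutationSpec | None = None,
                   start=None, max_steps: int = DEFAULT_MAX_STEPS,
                   seed: int = 0, abm_config: AbmSelectionConfig | None = None,
                   B=None, cost_coefficient: float = 0.0,
                   hit_rate: float = 1.0) -> TrajectoryRecord:
    """Run one mutate-select-replace adaptive walk.

    ``backend`` is ``"abm"`` or ``"simplified"``.  The walk starts from the
    fully susceptible state (all sensitivities 1) unless ``start`` is
    given, and runs for ``max_steps`` proposals or until extinction.
    Per-step randomness derives from ``(seed, step)`` so trajectories are
    reproducible and extendable.
    """
    if backend not in ("abm", "simplified"):
        raise ValueError(f"unknown backend {backend!r}")
    attacker = np.atleast_1d(np.asarray(attacker, dtype=float))
    spec = spec or MutationSpec()
    if start is None:
        start = np.ones_like(attacker)
    resident = np.atleast_1d(np.asarray(start, dtype=float)).copy()
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")

    states = [resident.copy()]
    outcomes: list[Outcome] = []
    terminated_by = "completed"
    for step in range(max_steps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), step]))
        mutant = propose_mutation(resident, spec, rng)
        if backend == "simplified":
            outcome = simplified_selection_step(resident, mutant, attacker, B,
                                                cost_coefficient=cost_coefficient,
                                                hit_rate=hit_rate)
        else:
            cfg = abm_config or AbmSelectionConfig()
            step_seed = int(np.random.SeedSequence([int(seed), step, 1]).generate_state(1)[0] % 2**31)
            outcome = abm_selection_step(resident, mutant, attacker, cfg, step_seed)
        outcomes.append(outcome)
        if outcome is Outcome.FIXED:
            resident = mutant
        states.append(resident.copy())
        if outcome is Outcome.EXTINCT:
            terminated_by = "extinction"
            break

    record = TrajectoryRecord(states=states, outcomes=outcomes,
                              terminated_by=terminated_by, attacker=attacker)
    record.endpoint_n_hits = n_hits(record.endpoint, attacker)
    return record


def run_trajectories(backend: str, attacker, n_trajectories: int,
                     spec: MutationSpec | None = None, start=None,
                     max_steps: int = DEFAULT_MAX_STEPS, seed: int = 0,
                     abm_config: AbmSelectionConfig | None = None,
                     B=None, cost_coefficient: float = 0.0,
                     hit_rate: float = 1.0) -> list[TrajectoryRecord]:
    """Independent replicate walks with per-trajectory derived seeds."""
    seeds = [int(s.generate_state(1)[0] % 2**31)
             for s in np.random.SeedSequence(int(seed)).spawn(n_trajectories)]
    return [run_trajectory(backend, attacker, spec, start, max_steps, s,
                           abm_config, B, cost_coefficient, hit_rate) for s in seeds]


def trajectory_summary(records: list[TrajectoryRecord]) -> pd.DataFrame:
    """Per-trajectory endpoint table with resistance-threshold flags."""
    if not records:
        raise ValueError("no trajectories to summarise")
    rows = []
    for k, rec in enumerate(records):
        row = {
            "trajectory": k,
            "steps": len(rec.outcomes),
            "fixations": sum(o is Outcome.FIXED for o in rec.outcomes),
            "extinct": rec.terminated_by == "extinction",
            "endpoint_n_hits": rec.endpoint_n_hits,
            "reached_nhits_2": bool(rec.endpoint_n_hits >= 2),
            "exceeded_nhits_20": bool(rec.endpoint_n_hits > 20),
        }
        row.update({f"a_{i + 1}": float(v) for i, v in enumerate(rec.endpoint)})
        rows.append(row)
    return pd.DataFrame(rows)
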