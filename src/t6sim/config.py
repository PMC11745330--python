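"""Run configuration: schema, defaults, validation, TOML/JSON parsing.

Every run is described by a :class:`RunConfig` naming an experiment kind
(``compete``, ``evolve``, ``sweep``, or ``analytic``) plus the module
parameters for that kind.  Configurations round-trip through
:meth:`RunConfig.to_mapping` / :func:`parse_config`, and files may be TOML
or JSON.  Unknown keys and out-of-range values are rejected with the
offending key named.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .competition import (DEFAULT_ARENA_RADIUS, DEFAULT_DT, DEFAULT_DURATION,
                          DEFAULT_K_FIRE, DEFAULT_K_LYSIS, DEFAULT_REPLICATES,
                          CompetitionConfig, StrainSpec)
from .evolution import (ABM_DURATION, ABM_SEED_COUNTS, DEFAULT_MAX_STEPS,
                        DEFAULT_SIGMA, AbmSelectionConfig, MutationSpec)
from .firing import FiringRates

KINDS = ("compete", "evolve", "sweep", "analytic")

# canonical three-strain setup: a single-toxin-A attacker, a fully
# susceptible strain, and a rare mutant immune to toxin A, mixed 500:90:10
DEFAULT_STRAINS = (
    {"label": "attacker", "count": 500, "sensitivity": [0.0, 0.0], "arsenal": [1.0, 0.0]},
    {"label": "susceptible", "count": 90, "sensitivity": [1.0, 1.0]},
    {"label": "mutant", "count": 10, "sensitivity": [0.0, 1.0]},
)


class ConfigError(ValueError):
    """A configuration key is unknown, missing, or out of range."""


@dataclass(frozen=True)
class EvolveParams:
    backend: str = "simplified"
    attacker: tuple[float, ...] = (1.0, 0.0)
    sigma: float = DEFAULT_SIGMA
    max_steps: int = DEFAULT_MAX_STEPS
    n_trajectories: int = 30
    counts: tuple[int, int, int] = ABM_SEED_COUNTS
    duration: float = ABM_DURATION

    def mutation_spec(self) -> MutationSpec:
        return MutationSpec(sigma=self.sigma)

    def abm_config(self, rates: FiringRates, arena_radius: float,
                   dt: float) -> AbmSelectionConfig:
        return AbmSelectionConfig(counts=self.counts, duration=self.duration,
                                  arena_radius=arena_radius, dt=dt, rates=rates)


@dataclass(frozen=True)
class RunConfig:
    kind: str = "compete"
    seed: int = 0
    competition: CompetitionConfig = None  # type: ignore[assignment]
    evolve: EvolveParams = field(default_factory=EvolveParams)

    def to_mapping(self) -> dict[str, Any]:
        comp = self.competition
        return {
            "kind": self.kind,
            "seed": self.seed,
            "competition": {
                "arena_radius": comp.arena_radius,
                "duration": comp.duration,
                "dt": comp.dt,
                "k_fire": comp.rates.k_fire,
                "k_lysis": comp.rates.k_lysis,
                "cost_coefficient": comp.cost_coefficient,
                "replicates": comp.replicates,
                "direction_mode": comp.direction_mode,
                "B": None if comp.B is None else [list(row) for row in comp.B],
            },
            "strains": [
                {"label": s.label, "count": s.count,
                 "sensitivity": list(map(float, s.sensitivity)),
                 **({"arsenal": list(map(float, s.arsenal))} if s.arsenal is not None else {}),
                 "growth_rate": s.growth_rate}
                for s in comp.strains
            ],
            "evolve": {
                "backend": self.evolve.backend,
                "attacker": list(self.evolve.attacker),
                "sigma": self.evolve.sigma,
                "max_steps": self.evolve.max_steps,
                "n_trajectories": self.evolve.n_trajectories,
                "counts": list(self.evolve.counts),
                "duration": self.evolve.duration,
            },
        }


def _check_keys(mapping: Mapping, allowed: set[str], context: str):
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")


def _strain_from_mapping(m: Mapping, idx: int) -> StrainSpec:
    _check_keys(m, {"label", "count", "sensitivity", "arsenal", "growth_rate"},
                f"strains[{idx}]")
    try:
        return StrainSpec(
            label=str(m.get("label", f"strain{idx}")),
            count=int(m.get("count", 0)),
            sensitivity=np.asarray(m["sensitivity"], dtype=float),
            arsenal=None if m.get("arsenal") is None else np.asarray(m["arsenal"], dtype=float),
            growth_rate=float(m.get("growth_rate", np.log(2.0) / 2.5)),
        )
    except KeyError as exc:
        raise ConfigError(f"strains[{idx}] missing key {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"strains[{idx}]: {exc}") from exc


def parse_config(source: str | Path | Mapping | None = None) -> RunConfig:
    """Build a fully validated :class:`RunConfig`.

    ``source`` may be a mapping, a path to a ``.toml`` or ``.json`` file,
    or ``None``/empty for the all-defaults configuration.
    """
    if source is None:
        data: Mapping = {}
    elif isinstance(source, Mapping):
        data = source
    else:
        path = Path(source)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        elif path.suffix == ".json":
            data = json.loads(path.read_text())
        else:
            raise ConfigError(f"unsupported config format: {path.suffix or path}")

    _check_keys(data, {"kind", "seed", "competition", "strains", "evolve"}, "config")
    kind = str(data.get("kind", "compete"))
    if kind not in KINDS:
        raise ConfigError(f"kind must be one of {KINDS}, got {kind!r}")
    seed = int(data.get("seed", 0))

    comp = dict(data.get("competition", {}))
    _check_keys(comp, {"arena_radius", "duration", "dt", "k_fire", "k_lysis",
                       "cost_coefficient", "replicates", "direction_mode", "B"},
                "competition")
    strains_raw = data.get("strains", DEFAULT_STRAINS)
    strains = tuple(_strain_from_mapping(m, i) for i, m in enumerate(strains_raw))
    if "k_fire" in comp and comp["k_fire"] < 0:
        raise ConfigError("competition.k_fire must be >= 0")
    if "k_lysis" in comp and comp["k_lysis"] <= 0:
        raise ConfigError("competition.k_lysis must be > 0")
    try:
        competition = CompetitionConfig(
            strains=strains,
            arena_radius=float(comp.get("arena_radius", DEFAULT_ARENA_RADIUS)),
            duration=float(comp.get("duration", DEFAULT_DURATION)),
            dt=float(comp.get("dt", DEFAULT_DT)),
            rates=FiringRates(float(comp.get("k_fire", DEFAULT_K_FIRE)),
                              float(comp.get("k_lysis", DEFAULT_K_LYSIS))),
            B=None if comp.get("B") is None else np.asarray(comp["B"], dtype=float),
            cost_coefficient=float(comp.get("cost_coefficient", 0.0)),
            seed=seed,
            replicates=int(comp.get("replicates", DEFAULT_REPLICATES)),
            direction_mode=str(comp.get("direction_mode", "normal")),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    ev = dict(data.get("evolve", {}))
    _check_keys(ev, {"backend", "attacker", "sigma", "max_steps",
                     "n_trajectories", "counts", "duration"}, "evolve")
    backend = str(ev.get("backend", "simplified"))
    if backend not in ("abm", "simplified"):
        raise ConfigError(f"evolve.backend must be 'abm' or 'simplified', got {backend!r}")
    sigma = float(ev.get("sigma", DEFAULT_SIGMA))
    if sigma < 0:
        raise ConfigError("evolve.sigma must be >= 0")
    evolve = EvolveParams(
        backend=backend,
        attacker=tuple(float(x) for x in ev.get("attacker", (1.0, 0.0))),
        sigma=sigma,
        max_steps=int(ev.get("max_steps", DEFAULT_MAX_STEPS)),
        n_trajectories=int(ev.get("n_trajectories", 30)),
        counts=tuple(int(x) for x in ev.get("counts", ABM_SEED_COUNTS)),
        duration=float(ev.get("duration", ABM_DURATION)),
    )
    return RunConfig(kind=kind, seed=seed, competition=competition, evolve=evolve)
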