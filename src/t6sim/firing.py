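"""Stochastic T6SS firing, needle hit resolution, and corpse lysis.

Each timestep, every living attacker fires a Poisson(``k_fire * dt``)
number of needles from uniform-random points on its membrane.  A needle
has length one cell radius (``R = 0.5`` um) and points along the outward
surface normal at its base (a uniform outward direction is available as an
alternative convention).  A line-segment hit test against the spatial grid
finds, for each needle, the first cell whose capsule the segment enters;
that cell receives the firer strain's full per-hit dose vector, unless it
belongs to the firer's own strain (clonemates are perfectly immune).
Dead-but-unlysed cells still absorb hits ("corpse barrier"); corpses are
physically removed a fixed delay ``1/k_lysis`` after death.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cells import Population, SpatialGrid, RodCell
from .geometry import needle_entry_parameter, segment_endpoints


@dataclass(frozen=True)
class FiringRates:
    """Population firing rate and corpse-removal rate."""

    k_fire: float   # firings cell^-1 h^-1
    k_lysis: float  # h^-1; corpses persist for 1/k_lysis hours

    def __post_init__(self):
        if self.k_fire < 0:
            raise ValueError("k_fire must be >= 0")
        if self.k_lysis <= 0:
            raise ValueError("k_lysis must be > 0")


@dataclass(frozen=True)
class Needle:
    firer_id: int
    base: np.ndarray       # point on the firer's membrane
    direction: np.ndarray  # unit vector
    needle_length: float   # = cell radius


@dataclass(frozen=True)
class HitEvent:
    needle: Needle
    target_id: int
    hit_distance: float


def sample_firing_counts(pop: Population, attacker_mask: np.ndarray,
                         k_fire: float, dt: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-cell Poisson(k_fire * dt) firing counts; corpses never fire."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    counts = np.zeros(len(pop), dtype=np.int64)
    firers = attacker_mask & pop.alive
    counts[firers] = rng.poisson(k_fire * dt, int(firers.sum()))
    return counts


def _boundary_points(pos, angle, length, radius, u_perim, rng):
    """Map uniform perimeter coordinates to membrane points and normals.

    The capsule perimeter splits into two straight flanks of length ``L``
    and two end-cap arcs of combined length ``2 pi R``.
    """
    L = np.asarray(length, dtype=float)
    perim = 2.0 * L + 2.0 * np.pi * radius
    s = u_perim * perim
    axis = np.stack([np.cos(angle), np.sin(angle)], axis=-1)
    perp = np.stack([-np.sin(angle), np.cos(angle)], axis=-1)
    pos = np.asarray(pos, dtype=float)

    base = np.empty_like(pos)
    normal = np.empty_like(pos)

    on_top = s < L
    on_bot = (~on_top) & (s < 2.0 * L)
    on_cap = ~(on_top | on_bot)

    for mask, sign, off in ((on_top, +1.0, 0.0), (on_bot, -1.0, 1.0)):
        x = s[mask] - off * L[mask] - 0.5 * L[mask]
        base[mask] = pos[mask] + x[:, None] * axis[mask] + sign * radius * perp[mask]
        normal[mask] = sign * perp[mask]

    # end caps: arc coordinate phi in [0, 2 pi); phi in (-pi/2, pi/2)
    # relative to the axis direction lands on the +end cap, the rest on -end
    phi = (s[on_cap] - 2.0 * L[on_cap]) / radius - 0.5 * np.pi
    plus_end = np.cos(phi) >= 0.0
    cap_sign = np.where(plus_end, 1.0, -1.0)
    cap_center = pos[on_cap] + (cap_sign * 0.5 * L[on_cap])[:, None] * axis[on_cap]
    ca = np.asarray(angle)[on_cap] + phi
    radial = np.stack([np.cos(ca), np.sin(ca)], axis=-1)
    base[on_cap] = cap_center + radius * radial
    normal[on_cap] = radial
    return base, normal


def spawn_needles_population(pop: Population, counts: np.ndarray,
                             rng: np.random.Generator,
                             direction_mode: str = "normal"):
    """Spawn all needles for one timestep as flat arrays.

    Returns ``(firer_idx, base, direction)``; needle length equals the cell
    radius.  ``direction_mode`` is ``"normal"`` (outward surface normal at
    the base point) or ``"uniform"`` (uniform random direction in the
    outward half-plane).
    """
    firer_idx = np.repeat(np.arange(len(pop)), counts)
    n = firer_idx.size
    if n == 0:
        return firer_idx, np.empty((0, 2)), np.empty((0, 2))
    u = rng.random(n)
    base, normal = _boundary_points(pop.pos[firer_idx], pop.angle[firer_idx],
                                    pop.length[firer_idx], pop.radius, u, rng)
    if direction_mode == "normal":
        direction = normal
    elif direction_mode == "uniform":
        theta = rng.uniform(-0.5 * np.pi, 0.5 * np.pi, n)
        ct, st = np.cos(theta), np.sin(theta)
        # rotate the outward normal by theta in (-pi/2, pi/2)
        direction = np.stack([ct * normal[:, 0] - st * normal[:, 1],
                              st * normal[:, 0] + ct * normal[:, 1]], axis=-1)
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    return firer_idx, base, direction


def spawn_needles(cell: RodCell, n: int, rng: np.random.Generator,
                  direction_mode: str = "normal") -> list[Needle]:
    """Single-cell convenience wrapper returning :class:`Needle` records."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    u = rng.random(n)
    base, normal = _boundary_points(np.tile(cell.center, (n, 1)),
                                    np.full(n, cell.angle), np.full(n, cell.length),
                                    cell.radius, u, rng)
    if direction_mode == "uniform":
        theta = rng.uniform(-0.5 * np.pi, 0.5 * np.pi, n)
        ct, st = np.cos(theta), np.sin(theta)
        normal = np.stack([ct * normal[:, 0] - st * normal[:, 1],
                           st * normal[:, 0] + ct * normal[:, 1]], axis=-1)
    return [Needle(firer_id=cell.id, base=base[k], direction=normal[k],
                   needle_length=cell.radius) for k in range(n)]


def resolve_hits(firer_idx: np.ndarray, base: np.ndarray, direction: np.ndarray,
                 pop: Population, grid: SpatialGrid):
    """First-cell-struck resolution for a batch of needles.

    For every needle, candidate targets come from the grid bins overlapped
    by the needle's bounding box; the needle strikes the candidate with the
    smallest entry parameter along its length, excluding the firer itself.
    Corpses (dead, unlysed cells) are valid targets.  Returns
    ``(needle_idx, target_idx, hit_distance)`` arrays for the needles that
    struck something.
    """
    n_needles = firer_idx.size
    if n_needles == 0 or len(pop) == 0:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    reach = pop.radius
    tip = base + reach * direction
    lo = np.minimum(base, tip) - pop.radius
    hi = np.maximum(base, tip) + pop.radius

    pair_needle: list[np.ndarray] = []
    pair_target: list[np.ndarray] = []
    for k in range(n_needles):
        cand = grid.query_aabb(lo[k], hi[k])
        cand = cand[cand != firer_idx[k]]
        if cand.size:
            pair_needle.append(np.full(cand.size, k, dtype=np.int64))
            pair_target.append(cand)
    if not pair_needle:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    nk = np.concatenate(pair_needle)
    tk = np.concatenate(pair_target)

    p1, p2 = pop.endpoints
    t_entry = needle_entry_parameter(base[nk], direction[nk], p1[tk], p2[tk],
                                     pop.radius, reach)
    hit = np.isfinite(t_entry)
    nk, tk, t_entry = nk[hit], tk[hit], t_entry[hit]
    if nk.size == 0:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0),)
    order = np.lexsort((t_entry, nk))
    nk, tk, t_entry = nk[order], tk[order], t_entry[order]
    first = np.ones(nk.size, dtype=bool)
    first[1:] = nk[1:] != nk[:-1]
    return nk[first], tk[first], t_entry[first]


def intoxicate(needle_firer: np.ndarray, target_idx: np.ndarray,
               pop: Population, arsenal_by_strain: np.ndarray,
               sensitivity_by_strain: np.ndarray,
               B: np.ndarray | None, now: float) -> int:
    """Translocate doses for resolved hits and mark newly dead cells.

    ``arsenal_by_strain`` is ``(n_strains, n_toxins)`` with zero rows for
    non-attackers; ``sensitivity_by_strain`` likewise.  Hits between
    clonemates (same strain index) translocate nothing.  Doses landing on
    corpses still accumulate (overkill is harmless).  Returns the number of
    cells newly killed.
    """
    if target_idx.size == 0:
        return 0
    firer_strain = pop.strain[needle_firer]
    target_strain = pop.strain[target_idx]
    effective = firer_strain != target_strain
    ti = target_idx[effective]
    doses = arsenal_by_strain[firer_strain[effective]]
    if ti.size == 0:
        return 0
    np.add.at(pop.toxins, ti, doses)

    touched = np.unique(ti)
    x = pop.toxins[touched]
    a = sensitivity_by_strain[pop.strain[touched]]
    I = 1.0 - np.einsum("ij,ij->i", a, x)
    if B is not None and np.any(B):
        I -= np.einsum("ij,jk,ik->i", x, B, x)
    newly_dead = (I <= 0.0) & pop.alive[touched]
    idx_dead = touched[newly_dead]
    pop.alive[idx_dead] = False
    pop.death_time[idx_dead] = now
    pop.growth_rate[idx_dead] = 0.0
    return int(idx_dead.size)


def cull_and_lyse(pop: Population, now: float, k_lysis: float) -> int:
    """Remove corpses dead for at least ``1/k_lysis`` hours."""
    if k_lysis <= 0:
        raise ValueError("k_lysis must be > 0")
    expired = (~pop.alive) & (now - pop.death_time >= 1.0 / k_lysis)
    n = int(expired.sum())
    if n:
        pop.remove(expired)
    return n
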