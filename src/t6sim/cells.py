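"""Rod-cell biophysics on an unbounded 2-D plane.

Cells are elongating spherocylindrical rods of fixed radius ``R = 0.5`` um
and variable axis-segment length ``L``.  In this 2-D setting a cell's
"volume" ``V`` is its capsule footprint area, ``V = 2 R L + pi R^2``, so the
``V <-> L`` conversion is closed-form.  Volume grows exponentially at a
per-cell specific rate; on reaching twice the birth volume (plus uniform
noise) the cell divides lengthwise into two equal daughters.

Mechanical exclusion is enforced by a position-based relaxation that
iteratively removes pairwise capsule overlap with small damped translations
and rotations; neighbour candidates come from an unbounded square spatial
grid (default bin size 10 um).

The :class:`Population` container is a struct-of-arrays over all cells so
the simulation loop can run vectorised; :class:`RodCell` is the
corresponding single-cell record used at the API surface and in tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._kernels import max_pair_overlap, relax_chunk
from .geometry import segment_endpoints

CELL_RADIUS = 0.5          # um, fixed for all cells
DEFAULT_BIRTH_LENGTH = 1.0  # um axis-segment length of a newborn cell
DEFAULT_GROWTH_RATE = np.log(2.0) / 2.5  # 1/h: one doubling per 2.5 h
DIVISION_NOISE_FRACTION = 0.1  # eta ~ U[-f*V0, +f*V0]
GRID_CELL_SIZE = 10.0      # um


def volume_from_length(length, radius: float = CELL_RADIUS):
    """Capsule footprint area for axis length ``L``: 2RL + pi R^2."""
    return 2.0 * radius * np.asarray(length, dtype=float) + np.pi * radius**2


def length_from_volume(volume, radius: float = CELL_RADIUS):
    """Inverse of :func:`volume_from_length` (clipped at L = 0)."""
    L = (np.asarray(volume, dtype=float) - np.pi * radius**2) / (2.0 * radius)
    return np.maximum(L, 0.0)


DEFAULT_BIRTH_VOLUME = float(volume_from_length(DEFAULT_BIRTH_LENGTH))


@dataclass
class RodCell:
    """A single spherocylindrical cell."""

    id: int
    strain: int
    center: np.ndarray
    angle: float
    length: float
    growth_rate: float = DEFAULT_GROWTH_RATE
    birth_volume: float = DEFAULT_BIRTH_VOLUME
    division_noise: float = 0.0
    toxins: np.ndarray = field(default_factory=lambda: np.zeros(1))
    alive: bool = True
    death_time: float | None = None
    radius: float = CELL_RADIUS

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        self.toxins = np.asarray(self.toxins, dtype=float)

    @property
    def volume(self) -> float:
        return float(volume_from_length(self.length, self.radius))

    @property
    def direction(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    @property
    def endpoints(self):
        half = 0.5 * self.length * self.direction
        return self.center - half, self.center + half


def grow_cell(cell: RodCell, dt: float, multiplier: float = 1.0) -> RodCell:
    """Exponential volume growth over ``dt`` hours; dead cells unchanged."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not cell.alive or dt == 0.0:
        return cell
    V = cell.volume * np.exp(cell.growth_rate * multiplier * dt)
    cell.length = float(length_from_volume(V, cell.radius))
    return cell


def divide_if_ready(cell: RodCell, rng: np.random.Generator, new_id: int = -1,
                    noise_fraction: float = DIVISION_NOISE_FRACTION):
    """Split a cell once it reaches volume ``2 V0 + eta``.

    Returns a list of one (no division) or two daughters.  Daughters are
    equal-volume, placed end-to-end along the parent axis with the parent's
    orientation, record their own birth volume, draw fresh division noise,
    and copy the parent's accumulated toxin load.  The first daughter keeps
    the parent id; the second takes ``new_id``.
    """
    if not cell.alive:
        return [cell]
    V = cell.volume
    if V < 2.0 * cell.birth_volume + cell.division_noise:
        return [cell]
    V_half = 0.5 * V
    L_d = float(length_from_volume(V_half, cell.radius))
    offset = 0.25 * (cell.length + 2.0 * cell.radius) * cell.direction
    daughters = []
    for sign, cid in ((-1.0, cell.id), (+1.0, new_id)):
        eta = float(rng.uniform(-noise_fraction, noise_fraction) * V_half)
        daughters.append(RodCell(
            id=cid, strain=cell.strain, center=cell.center + sign * offset,
            angle=cell.angle, length=L_d, growth_rate=cell.growth_rate,
            birth_volume=V_half, division_noise=eta,
            toxins=cell.toxins.copy(), alive=True, radius=cell.radius,
        ))
    return daughters


class Population:
    """Struct-of-arrays container for all cells in a simulation."""

    def __init__(self, n_toxins: int, radius: float = CELL_RADIUS):
        self.n_toxins = int(n_toxins)
        self.radius = float(radius)
        self.t = 0.0
        self.ids = np.empty(0, dtype=np.int64)
        self.strain = np.empty(0, dtype=np.int64)
        self.pos = np.empty((0, 2), dtype=float)
        self.angle = np.empty(0, dtype=float)
        self.length = np.empty(0, dtype=float)
        self.growth_rate = np.empty(0, dtype=float)
        self.birth_volume = np.empty(0, dtype=float)
        self.division_noise = np.empty(0, dtype=float)
        self.toxins = np.empty((0, self.n_toxins), dtype=float)
        self.alive = np.empty(0, dtype=bool)
        self.death_time = np.empty(0, dtype=float)  # NaN while alive
        self._next_id = 0
        self.born_per_strain: dict[int, int] = {}
        self.lysed_per_strain: dict[int, int] = {}

    # -- construction -------------------------------------------------

    def add_cells(self, strain, pos, angle, length, growth_rate=DEFAULT_GROWTH_RATE,
                  birth_volume=None, division_noise=None, toxins=None, rng=None):
        """Append newborn cells; scalar arguments broadcast."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        n = pos.shape[0]
        strain = np.broadcast_to(np.asarray(strain, dtype=np.int64), n).copy()
        angle = np.broadcast_to(np.asarray(angle, dtype=float), n).copy()
        length = np.broadcast_to(np.asarray(length, dtype=float), n).copy()
        growth_rate = np.broadcast_to(np.asarray(growth_rate, dtype=float), n).copy()
        if birth_volume is None:
            birth_volume = volume_from_length(length, self.radius)
        birth_volume = np.broadcast_to(np.asarray(birth_volume, dtype=float), n).copy()
        if division_noise is None:
            if rng is None:
                division_noise = np.zeros(n)
            else:
                division_noise = rng.uniform(-DIVISION_NOISE_FRACTION,
                                             DIVISION_NOISE_FRACTION, n) * birth_volume
        division_noise = np.broadcast_to(np.asarray(division_noise, dtype=float), n).copy()
        if toxins is None:
            toxins = np.zeros((n, self.n_toxins))
        toxins = np.asarray(toxins, dtype=float).reshape(n, self.n_toxins)
        ids = np.arange(self._next_id, self._next_id + n, dtype=np.int64)
        self._next_id += n

        self.ids = np.concatenate([self.ids, ids])
        self.strain = np.concatenate([self.strain, strain])
        self.pos = np.concatenate([self.pos, pos])
        self.angle = np.concatenate([self.angle, angle])
        self.length = np.concatenate([self.length, length])
        self.growth_rate = np.concatenate([self.growth_rate, growth_rate])
        self.birth_volume = np.concatenate([self.birth_volume, birth_volume])
        self.division_noise = np.concatenate([self.division_noise, division_noise])
        self.toxins = np.concatenate([self.toxins, toxins])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        self.death_time = np.concatenate([self.death_time, np.full(n, np.nan)])
        for s, cnt in zip(*np.unique(strain, return_counts=True)):
            self.born_per_strain[int(s)] = self.born_per_strain.get(int(s), 0) + int(cnt)
        return ids

    @classmethod
    def from_cells(cls, cells: list[RodCell], n_toxins: int | None = None) -> "Population":
        if n_toxins is None:
            n_toxins = cells[0].toxins.size if cells else 1
        pop = cls(n_toxins=n_toxins, radius=cells[0].radius if cells else CELL_RADIUS)
        for c in cells:
            pop.add_cells(c.strain, c.center[None, :], c.angle, c.length,
                          growth_rate=c.growth_rate, birth_volume=c.birth_volume,
                          division_noise=c.division_noise, toxins=c.toxins[None, :])
            pop.alive[-1] = c.alive
            pop.death_time[-1] = np.nan if c.death_time is None else c.death_time
            pop.ids[-1] = c.id
        pop._next_id = int(pop.ids.max() + 1) if len(pop) else 0
        return pop

    # -- views ---------------------------------------------------------

    def __len__(self) -> int:
        return self.ids.size

    def cell(self, i: int) -> RodCell:
        """Single-cell record view (copy) of row ``i``."""
        dt = self.death_time[i]
        return RodCell(
            id=int(self.ids[i]), strain=int(self.strain[i]),
            center=self.pos[i].copy(), angle=float(self.angle[i]),
            length=float(self.length[i]), growth_rate=float(self.growth_rate[i]),
            birth_volume=float(self.birth_volume[i]),
            division_noise=float(self.division_noise[i]),
            toxins=self.toxins[i].copy(), alive=bool(self.alive[i]),
            death_time=None if np.isnan(dt) else float(dt), radius=self.radius,
        )

    def cells(self) -> list[RodCell]:
        return [self.cell(i) for i in range(len(self))]

    @property
    def volume(self) -> np.ndarray:
        return volume_from_length(self.length, self.radius)

    @property
    def endpoints(self):
        return segment_endpoints(self.pos, self.angle, self.length)

    def alive_counts(self, n_strains: int) -> np.ndarray:
        return np.bincount(self.strain[self.alive], minlength=n_strains)

    # -- dynamics ------------------------------------------------------

    def grow(self, dt: float, rate_multiplier: np.ndarray | None = None):
        """Vectorised exponential growth; dead cells do not grow."""
        if dt < 0:
            raise ValueError("dt must be >= 0")
        mult = 1.0 if rate_multiplier is None else rate_multiplier[self.strain]
        k = np.where(self.alive, self.growth_rate * mult, 0.0)
        V = self.volume * np.exp(k * dt)
        self.length = length_from_volume(V, self.radius)

    def divide(self, rng: np.random.Generator,
               noise_fraction: float = DIVISION_NOISE_FRACTION) -> int:
        """Divide every cell at or past its division volume; returns count."""
        V = self.volume
        ready = self.alive & (V >= 2.0 * self.birth_volume + self.division_noise)
        idx = np.flatnonzero(ready)
        if idx.size == 0:
            return 0
        V_half = 0.5 * V[idx]
        L_d = length_from_volume(V_half, self.radius)
        u = np.stack([np.cos(self.angle[idx]), np.sin(self.angle[idx])], axis=-1)
        offset = (0.25 * (self.length[idx] + 2.0 * self.radius))[:, None] * u
        center = self.pos[idx].copy()

        # parent row becomes the first daughter
        self.pos[idx] = center - offset
        self.length[idx] = L_d
        self.birth_volume[idx] = V_half
        self.division_noise[idx] = rng.uniform(-noise_fraction, noise_fraction, idx.size) * V_half

        # second daughters appended as new rows (fresh ids, inherited toxins)
        self.add_cells(self.strain[idx], center + offset, self.angle[idx], L_d,
                       growth_rate=self.growth_rate[idx], birth_volume=V_half,
                       division_noise=rng.uniform(-noise_fraction, noise_fraction, idx.size) * V_half,
                       toxins=self.toxins[idx])
        # appended births were already tallied by add_cells; the first
        # daughter reuses the parent's row and id, so no extra tally needed
        return idx.size

    def remove(self, mask: np.ndarray):
        """Drop rows where ``mask`` is True (used for lysis)."""
        keep = ~mask
        for s, cnt in zip(*np.unique(self.strain[mask], return_counts=True)):
            self.lysed_per_strain[int(s)] = self.lysed_per_strain.get(int(s), 0) + int(cnt)
        self.ids = self.ids[keep]
        self.strain = self.strain[keep]
        self.pos = self.pos[keep]
        self.angle = self.angle[keep]
        self.length = self.length[keep]
        self.growth_rate = self.growth_rate[keep]
        self.birth_volume = self.birth_volume[keep]
        self.division_noise = self.division_noise[keep]
        self.toxins = self.toxins[keep]
        self.alive = self.alive[keep]
        self.death_time = self.death_time[keep]


class SpatialGrid:
    """Unbounded square binning grid over capsule extents.

    Every cell is registered in each bin overlapped by the axis-aligned
    bounding box of its capsule (axis segment inflated by the radius), so
    bin lookups return a superset of true geometric neighbours.
    """

    def __init__(self, cell_size: float = GRID_CELL_SIZE):
        if cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.cell_size = float(cell_size)
        self.bins: dict[tuple[int, int], list[int]] = {}

    def insert_aabb(self, idx: int, lo: np.ndarray, hi: np.ndarray):
        cs = self.cell_size
        x0, y0 = int(np.floor(lo[0] / cs)), int(np.floor(lo[1] / cs))
        x1, y1 = int(np.floor(hi[0] / cs)), int(np.floor(hi[1] / cs))
        for bx in range(x0, x1 + 1):
            for by in range(y0, y1 + 1):
                self.bins.setdefault((bx, by), []).append(idx)

    def query_aabb(self, lo, hi) -> np.ndarray:
        """Indices registered in any bin overlapping the box [lo, hi]."""
        cs = self.cell_size
        x0, y0 = int(np.floor(lo[0] / cs)), int(np.floor(lo[1] / cs))
        x1, y1 = int(np.floor(hi[0] / cs)), int(np.floor(hi[1] / cs))
        found: list[int] = []
        for bx in range(x0, x1 + 1):
            for by in range(y0, y1 + 1):
                found.extend(self.bins.get((bx, by), ()))
        return np.unique(np.asarray(found, dtype=np.int64))

    def candidate_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All unordered index pairs sharing at least one bin."""
        ii: list[np.ndarray] = []
        jj: list[np.ndarray] = []
        for members in self.bins.values():
            m = len(members)
            if m < 2:
                continue
            arr = np.asarray(members, dtype=np.int64)
            a, b = np.triu_indices(m, k=1)
            ii.append(arr[a])
            jj.append(arr[b])
        if not ii:
            return (np.empty(0, dtype=np.int64),) * 2
        i = np.concatenate(ii)
        j = np.concatenate(jj)
        lo = np.minimum(i, j)
        hi = np.maximum(i, j)
        stride = hi.max() + 1
        key = np.sort(lo * stride + hi)
        first = np.ones(key.size, dtype=bool)
        first[1:] = key[1:] != key[:-1]
        key = key[first]
        return key // stride, key % stride


def build_grid(pop: Population, cell_size: float = GRID_CELL_SIZE,
               slack: float = 0.0) -> SpatialGrid:
    """Register every cell's capsule AABB in a fresh grid (vectorised).

    ``slack`` inflates every AABB so the grid stays a valid neighbour
    superset while cells move up to that distance.
    """
    grid = SpatialGrid(cell_size)
    n = len(pop)
    if n == 0:
        return grid
    p1, p2 = pop.endpoints
    lo = np.minimum(p1, p2) - (pop.radius + slack)
    hi = np.maximum(p1, p2) + (pop.radius + slack)
    cs = grid.cell_size
    x0 = np.floor(lo[:, 0] / cs).astype(np.int64)
    y0 = np.floor(lo[:, 1] / cs).astype(np.int64)
    x1 = np.floor(hi[:, 0] / cs).astype(np.int64)
    y1 = np.floor(hi[:, 1] / cs).astype(np.int64)
    nx = x1 - x0 + 1
    ny = y1 - y0 + 1
    count = nx * ny
    idx = np.repeat(np.arange(n), count)
    start = np.repeat(np.cumsum(count) - count, count)
    off = np.arange(count.sum()) - start
    ny_rep = np.repeat(ny, count)
    bx = np.repeat(x0, count) + off // ny_rep
    by = np.repeat(y0, count) + off % ny_rep
    order = np.lexsort((by, bx))
    bx, by, idx = bx[order], by[order], idx[order]
    boundary = np.flatnonzero((bx[1:] != bx[:-1]) | (by[1:] != by[:-1])) + 1
    starts = np.concatenate([[0], boundary, [bx.size]])
    for a, b in zip(starts[:-1], starts[1:]):
        grid.bins[(int(bx[a]), int(by[a]))] = idx[a:b].tolist()
    return grid


def relax_overlaps(pop: Population, tolerance: float = 0.02,
                   max_iterations: int = 100, damping: float = 0.7,
                   grid_cell_size: float = GRID_CELL_SIZE) -> int:
    """Iteratively remove pairwise capsule overlap by damped displacements.

    Each iteration finds the closest points of every candidate capsule
    pair; overlapping pairs are pushed apart symmetrically along the
    contact normal by half the (damped) penetration depth, with a matching
    small rotation from the contact torque.  Lengths, volumes, and life
    status are never modified.  Returns the number of iterations used;
    warns (without raising) if the tolerance is not met in
    ``max_iterations``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    n = len(pop)
    if n < 2:
        return 0

    margin = 2.0   # um of per-cell travel tolerated before the pruned list goes stale
    slack = 4.0    # um of per-cell travel tolerated before the grid itself goes stale

    # the grid and its deduplicated candidate list are built once (with
    # slack so they survive cell movement); the compiled kernel iterates on
    # a distance-pruned view and hands control back whenever accumulated
    # movement threatens the pruning margin
    def full_pairs():
        return build_grid(pop, grid_cell_size, slack=slack).candidate_pairs()

    def prune(i, j):
        if i.size == 0:
            return i, j
        sep = pop.pos[i] - pop.pos[j]
        dc2 = np.einsum("ij,ij->i", sep, sep)
        reach = 0.5 * (pop.length[i] + pop.length[j]) + 2.0 * pop.radius + margin
        near = dc2 <= reach * reach
        return i[near], j[near]

    i_all, j_all = full_pairs()
    i_idx, j_idx = prune(i_all, j_all)
    inv_moment = 1.0 / (pop.length**2 / 12.0 + pop.radius**2)

    it_used = 0
    moved_since_grid = 0.0
    converged = i_idx.size == 0
    while it_used < max_iterations and not converged:
        done, moved, converged = relax_chunk(
            pop.pos, pop.angle, pop.length, i_idx, j_idx, pop.radius,
            tolerance, damping, inv_moment, max_iterations - it_used,
            0.5 * margin)
        it_used += done
        moved_since_grid += moved
        if converged:
            break
        if moved_since_grid > slack:
            i_all, j_all = full_pairs()
            moved_since_grid = 0.0
        i_idx, j_idx = prune(i_all, j_all)

    if not converged and i_idx.size:
        worst = float(max_pair_overlap(pop.pos, pop.angle, pop.length,
                                       i_idx, j_idx, pop.radius))
        if worst > tolerance:
            warnings.warn(
                f"overlap relaxation did not converge in {max_iterations} "
                f"iterations (worst residual overlap {worst:.4f} um)",
                stacklevel=2,
            )
    return it_used
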