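"""Closed-form multi-toxin dose-response model.

Each cell carries a scaled integrity variable ``I``, equal to 1 at birth.
T6SS hits translocate per-toxin doses ``d_i`` which accumulate as
intracellular amounts ``x_i``; damage is weighted by the cell's per-toxin
sensitivities ``a_i`` (1 = one unit of toxin is lethal, 0 = insensitive)
and, optionally, by pairwise toxin-interaction coefficients ``B_ij``
(synergy for ``B_ij > 0``, antagonism for ``B_ij < 0``; a nonzero diagonal
``B_ii`` encodes a nonlinear single-toxin dose-response):

    I = 1 - sum_i a_i x_i - sum_i sum_j B_ij x_i x_j

A cell dies once ``I <= 0``.  With purely additive toxins (``B = 0``) the
number of identical hits a cell can sustain -- its phenotypic resistance --
has the closed form

    N_hits = ceil( 1 / sum_i a_i d_i ),

infinite when the attacker's arsenal does not touch any sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SensitivityProfile",
    "Arsenal",
    "InteractionMatrix",
    "IntegrityState",
    "integrity",
    "n_hits",
    "apply_dose",
    "hits_to_death",
    "growth_multiplier",
]


def _vector(v, name: str, lo: float | None = None, hi: float | None = None) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(getattr(v, "a", getattr(v, "d", v)), dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if lo is not None and np.any(arr < lo):
        raise ValueError(f"{name} entries must be >= {lo}")
    if hi is not None and np.any(arr > hi):
        raise ValueError(f"{name} entries must be <= {hi}")
    return arr


def _matrix(B, n: int) -> np.ndarray:
    if B is None:
        return np.zeros((n, n))
    arr = np.asarray(getattr(B, "B", B), dtype=float)
    if arr.shape != (n, n):
        raise ValueError(f"interaction matrix must be {n}x{n}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("interaction matrix must be finite")
    return arr


@dataclass(frozen=True)
class SensitivityProfile:
    """Per-toxin sensitivities ``a_i`` in [0, 1] of a target cell type."""

    a: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "a", _vector(self.a, "sensitivity a", lo=0.0, hi=1.0))

    @property
    def n_toxins(self) -> int:
        return self.a.size


@dataclass(frozen=True)
class Arsenal:
    """Per-toxin doses ``d_i`` translocated per successful hit."""

    d: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "d", _vector(self.d, "dose d", lo=0.0))

    @property
    def n_toxins(self) -> int:
        return self.d.size


@dataclass(frozen=True)
class InteractionMatrix:
    """Pairwise toxin-interaction coefficients ``B_ij``."""

    B: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.B, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("B must be a square matrix")
        if not np.all(np.isfinite(arr)):
            raise ValueError("B must be finite")
        object.__setattr__(self, "B", arr)

    @classmethod
    def additive(cls, n_toxins: int) -> "InteractionMatrix":
        """The all-zero matrix: purely additive toxins."""
        return cls(np.zeros((n_toxins, n_toxins)))


@dataclass
class IntegrityState:
    """Accumulated toxin load and resulting integrity of one cell."""

    x: np.ndarray
    I: float = 1.0
    dead: bool = False

    @classmethod
    def fresh(cls, n_toxins: int) -> "IntegrityState":
        return cls(x=np.zeros(n_toxins), I=1.0, dead=False)


def integrity(a, x, B=None) -> float:
    """Evaluate I = 1 - sum_i a_i x_i - sum_ij B_ij x_i x_j.

    The double sum runs over all ordered pairs including ``i == j``, so a
    symmetric off-diagonal pair contributes twice.
    """
    av = _vector(a, "sensitivity a", lo=0.0, hi=1.0)
    xv = _vector(x, "toxin amounts x", lo=0.0)
    if av.size != xv.size:
        raise ValueError(f"sensitivity ({av.size}) and toxin amounts ({xv.size}) differ in length")
    Bm = _matrix(B, av.size)
    return float(1.0 - av @ xv - xv @ Bm @ xv)


def n_hits(a, d) -> float:
    """Phenotypic resistance: hits needed to kill, assuming additive toxins.

    Returns ``math.inf`` when the combined per-hit damage is zero.  The
    result is the smallest integer ``n`` with ``n * sum_i a_i d_i >= 1``
    evaluated in the same floating-point arithmetic the simulation's
    integrity bookkeeping uses, so the closed form and repeated dosing
    agree even at knife-edge reciprocals (e.g. ``1 / fl(1/3)`` evaluates
    just above 3, yet 3 hits already reach the death threshold).
    """
    av = _vector(a, "sensitivity a", lo=0.0, hi=1.0)
    dv = _vector(d, "dose d", lo=0.0)
    if av.size != dv.size:
        raise ValueError("sensitivity and dose vectors differ in length")
    s = float(av @ dv)
    if s == 0.0 or not math.isfinite(1.0 / s):
        return math.inf
    n = max(1, math.ceil(1.0 / s))
    while n > 1 and (n - 1) * s >= 1.0:
        n -= 1
    while n * s < 1.0:
        n += 1
    return n


def apply_dose(state: IntegrityState, a, d, B=None) -> IntegrityState:
    """Translocate one hit's doses into a cell and update its integrity.

    Doses accumulate even on already-dead (unlysed) cells -- overkill is
    harmless -- but death is sticky: once ``I`` reaches zero the cell stays
    dead.
    """
    dv = _vector(d, "dose d", lo=0.0)
    x_new = state.x + dv
    I_new = integrity(a, x_new, B)
    return IntegrityState(x=x_new, I=I_new, dead=bool(state.dead or I_new <= 0.0))


def hits_to_death(a, d, B=None, max_hits: int = 1_000_000) -> float:
    """Hits needed to kill by direct simulation of repeated dosing.

    Valid for arbitrary interaction matrices, unlike the additive
    closed form in :func:`n_hits`.  Returns ``math.inf`` if the cell can
    never die: under identical repeated doses integrity is a parabola in
    the hit count, so with a non-positive quadratic coefficient (net
    antagonism) an alive cell whose integrity has stopped falling is past
    the vertex and safe forever.  Also returns ``math.inf`` if the cell
    survives ``max_hits`` applications.
    """
    dv = _vector(d, "dose d", lo=0.0)
    Bm = _matrix(B, dv.size)
    quad = float(dv @ Bm @ dv)
    state = IntegrityState.fresh(dv.size)
    for k in range(1, max_hits + 1):
        prev_I = state.I
        state = apply_dose(state, a, d, B)
        if state.dead:
            return k
        if quad <= 0.0 and state.I >= prev_I:
            return math.inf
    return math.inf


def growth_multiplier(a, cost_coefficient: float) -> float:
    """Growth-rate multiplier for a resistance cost linear in insensitivity.

    ``max(0, 1 - c * sum_i (1 - a_i))``: fully sensitive cells pay nothing,
    and the penalty grows with total insensitivity.
    """
    if cost_coefficient < 0:
        raise ValueError("cost_coefficient must be >= 0")
    av = _vector(a, "sensitivity a", lo=0.0, hi=1.0)
    return float(max(0.0, 1.0 - cost_coefficient * np.sum(1.0 - av)))
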