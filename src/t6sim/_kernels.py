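"""Numba-compiled inner loops for the mechanical relaxation.

The overlap relaxation spends almost all of its time evaluating
capsule-capsule closest points and accumulating contact impulses over the
candidate-pair list, tens of iterations per timestep.  This module holds
that inner loop as a single compiled kernel; the Python layer in
:mod:`t6sim.cells` keeps the neighbour bookkeeping (grid build, pair
pruning) around it.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _seg_seg_closest(p1x, p1y, q1x, q1y, p2x, p2y, q2x, q2y):
    """Scalar closest points of segments [p1,q1] and [p2,q2].

    Returns (c1x, c1y, c2x, c2y, dist); clamped-parameter algorithm with
    degenerate segments handled explicitly.
    """
    d1x = q1x - p1x
    d1y = q1y - p1y
    d2x = q2x - p2x
    d2y = q2y - p2y
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    eps = 1e-12

    if a <= eps and e <= eps:
        s = 0.0
        t = 0.0
    elif a <= eps:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry
        if e <= eps:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y
            denom = a * e - b * b
            if denom > eps:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)

    c1x = p1x + s * d1x
    c1y = p1y + s * d1y
    c2x = p2x + t * d2x
    c2y = p2y + t * d2y
    dx = c1x - c2x
    dy = c1y - c2y
    return c1x, c1y, c2x, c2y, math.sqrt(dx * dx + dy * dy)


@njit(cache=True, fastmath=False)
def relax_chunk(pos, angle, length, i_idx, j_idx, radius, tolerance,
                damping, inv_moment, max_iters, move_budget):
    """Run damped contact-relaxation iterations in place.

    Iterates until no candidate pair overlaps beyond ``tolerance``, the
    iteration budget is spent, or accumulated worst-case movement exceeds
    ``move_budget`` (signalling the caller to refresh its pair list).
    Returns ``(iterations_done, moved, converged)``.
    """
    n = pos.shape[0]
    m = i_idx.size
    two_r = 2.0 * radius
    dpos = np.zeros((n, 2))
    dang = np.zeros(n)
    ex1 = np.empty(n)
    ey1 = np.empty(n)
    ex2 = np.empty(n)
    ey2 = np.empty(n)
    cos_a = np.empty(n)
    sin_a = np.empty(n)
    # per-cell accumulated travel bounds how stale the pair list can be
    cum = np.zeros(n)
    moved = 0.0
    it = 0
    converged = m == 0
    while it < max_iters and not converged and moved <= move_budget:
        it += 1
        for k in range(n):
            ca = math.cos(angle[k])
            sa = math.sin(angle[k])
            cos_a[k] = ca
            sin_a[k] = sa
            hx = 0.5 * length[k] * ca
            hy = 0.5 * length[k] * sa
            ex1[k] = pos[k, 0] - hx
            ey1[k] = pos[k, 1] - hy
            ex2[k] = pos[k, 0] + hx
            ey2[k] = pos[k, 1] + hy
            dpos[k, 0] = 0.0
            dpos[k, 1] = 0.0
            dang[k] = 0.0
        converged = True
        for k in range(m):
            a = i_idx[k]
            b = j_idx[k]
            cax, cay, cbx, cby, dist = _seg_seg_closest(
                ex1[a], ey1[a], ex2[a], ey2[a], ex1[b], ey1[b], ex2[b], ey2[b])
            ov = two_r - dist
            if ov <= tolerance:
                continue
            converged = False
            if dist > 1e-9:
                nx = (cbx - cax) / dist
                ny = (cby - cay) / dist
            else:
                # coincident axes: push perpendicular to cell a's axis
                nx = -sin_a[a]
                ny = cos_a[a]
            f = 0.5 * damping * ov
            fx = f * nx
            fy = f * ny
            dpos[a, 0] -= fx
            dpos[a, 1] -= fy
            dpos[b, 0] += fx
            dpos[b, 1] += fy
            rax = cax - pos[a, 0]
            ray = cay - pos[a, 1]
            rbx = cbx - pos[b, 0]
            rby = cby - pos[b, 1]
            dang[a] += damping * (rax * (-fy) - ray * (-fx)) * inv_moment[a]
            dang[b] += damping * (rbx * fy - rby * fx) * inv_moment[b]
        if converged:
            it -= 1  # the final sweep only verified convergence
            break
        moved = 0.0
        for k in range(n):
            pos[k, 0] += dpos[k, 0]
            pos[k, 1] += dpos[k, 1]
            angle[k] += dang[k]
            cum[k] += math.sqrt(dpos[k, 0] ** 2 + dpos[k, 1] ** 2) \
                + abs(dang[k]) * (0.5 * length[k] + radius)
            if cum[k] > moved:
                moved = cum[k]
    return it, moved, converged


@njit(cache=True, fastmath=False)
def max_pair_overlap(pos, angle, length, i_idx, j_idx, radius):
    """Worst capsule-capsule penetration over the given pairs."""
    worst = -1e30
    for k in range(i_idx.size):
        a = i_idx[k]
        b = j_idx[k]
        ca = math.cos(angle[a])
        sa = math.sin(angle[a])
        hx = 0.5 * length[a] * ca
        hy = 0.5 * length[a] * sa
        cb = math.cos(angle[b])
        sb = math.sin(angle[b])
        gx = 0.5 * length[b] * cb
        gy = 0.5 * length[b] * sb
        _, _, _, _, dist = _seg_seg_closest(
            pos[a, 0] - hx, pos[a, 1] - hy, pos[a, 0] + hx, pos[a, 1] + hy,
            pos[b, 0] - gx, pos[b, 1] - gy, pos[b, 0] + gx, pos[b, 1] + gy)
        ov = 2.0 * radius - dist
        if ov > worst:
            worst = ov
    return worst
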