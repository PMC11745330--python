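"""Vectorised 2-D capsule (spherocylinder cross-section) geometry kernels.

A rod cell of radius ``R`` and segment length ``L`` is represented by the
set of points within distance ``R`` of the axis segment joining its two
endpoints.  All kernels below operate on arrays of shape ``(n, 2)`` so that
pairwise interaction lists can be processed without Python-level loops.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Scalar z-component of the 2-D cross product, elementwise."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def segment_endpoints(pos: np.ndarray, angle: np.ndarray, length: np.ndarray):
    """Axis-segment endpoints of capsules centred at ``pos``.

    Returns ``(p1, p2)``, each of shape ``(n, 2)``.
    """
    u = np.stack([np.cos(angle), np.sin(angle)], axis=-1)
    half = 0.5 * np.asarray(length)[..., None] * u
    pos = np.asarray(pos, dtype=float)
    return pos - half, pos + half


def point_segment_closest(pt: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Closest point on segment [a, b] to ``pt`` and the distance to it."""
    pt, a, b = (np.asarray(x, dtype=float) for x in (pt, a, b))
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    t = np.where(denom > _EPS, np.einsum("...i,...i", pt - a, ab) / np.where(denom > _EPS, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(pt - closest, axis=-1)
    return closest, dist


def segment_segment_closest(p1, q1, p2, q2):
    """Closest points between segments [p1, q1] and [p2, q2] (vectorised).

    Implements the standard clamped-parameter algorithm for the closest
    points of two segments, with degenerate (point-like) segments handled
    explicitly.  Returns ``(c1, c2, dist)``.
    """
    p1, q1, p2, q2 = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (p1, q1, p2, q2))
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)

    a_ok = a > _EPS
    e_ok = e > _EPS
    a_safe = np.where(a_ok, a, 1.0)
    e_safe = np.where(e_ok, e, 1.0)

    denom = a * e - b * b
    s = np.where(denom > _EPS, np.clip((b * f - c * e) / np.where(denom > _EPS, denom, 1.0), 0.0, 1.0), 0.0)
    t = (b * s + f) / e_safe
    t_cl = np.clip(t, 0.0, 1.0)
    # when t was clamped, recompute s against the clamped t
    s = np.where(t != t_cl, np.clip((b * t_cl - c) / a_safe, 0.0, 1.0), s)
    t = t_cl

    # degenerate segments
    s = np.where(a_ok, s, 0.0)
    t = np.where(a_ok, t, np.clip(f / e_safe, 0.0, 1.0))
    t = np.where(e_ok, t, 0.0)
    s = np.where(e_ok, s, np.where(a_ok, np.clip(-c / a_safe, 0.0, 1.0), 0.0))

    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    dist = np.linalg.norm(c1 - c2, axis=-1)
    return c1, c2, dist


def capsule_overlap(p1, q1, p2, q2, radius_sum):
    """Penetration depth of two capsules (negative when separated)."""
    _, _, dist = segment_segment_closest(p1, q1, p2, q2)
    return radius_sum - dist


def needle_entry_parameter(base, direction, a, b, radius, reach):
    """Arc-length ``t`` at which a ray first enters a capsule, or +inf.

    The needle is the segment ``base + t * direction`` for ``t in [0, reach]``
    with ``direction`` a unit vector; the capsule has axis segment ``[a, b]``
    and radius ``radius``.  The entry parameter is the smallest ``t`` at
    which the needle tip lies on or inside the capsule surface.  Bases that
    already start inside the capsule report ``t = 0``.

    All arguments broadcast over a leading pair axis.
    """
    base, direction, a, b = (np.atleast_2d(np.asarray(x, dtype=float)) for x in (base, direction, a, b))
    n = base.shape[0]
    t_hit = np.full(n, np.inf)

    _, d0 = point_segment_closest(base, a, b)
    inside = d0 <= radius

    v = b - a
    vlen = np.linalg.norm(v, axis=-1)
    v_ok = vlen > _EPS
    vhat = v / np.where(v_ok, vlen, 1.0)[:, None]

    # crossing of the two lines parallel to the capsule axis at +/- radius
    s0 = cross2(vhat, base - a)
    su = cross2(vhat, direction)
    su_ok = np.abs(su) > _EPS
    su_safe = np.where(su_ok, su, 1.0)
    for side in (radius, -radius):
        t_line = (side - s0) / su_safe
        p = base + t_line[:, None] * direction
        proj = np.einsum("ij,ij->i", p - a, vhat)
        valid = v_ok & su_ok & (t_line >= 0.0) & (t_line <= reach) & (proj >= 0.0) & (proj <= vlen)
        t_hit = np.where(valid, np.minimum(t_hit, t_line), t_hit)

    # crossing of the end-cap circles (direction is unit, so the quadratic
    # in t has leading coefficient 1)
    for end in (a, b):
        w = base - end
        bq = np.einsum("ij,ij->i", direction, w)
        cq = np.einsum("ij,ij->i", w, w) - radius * radius
        disc = bq * bq - cq
        disc_ok = disc >= 0.0
        root = -bq - np.sqrt(np.where(disc_ok, disc, 0.0))
        valid = disc_ok & (root >= 0.0) & (root <= reach)
        t_hit = np.where(valid, np.minimum(t_hit, root), t_hit)

    return np.where(inside, 0.0, t_hit)
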