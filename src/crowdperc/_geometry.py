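"""Low-level geometric primitives compiled with numba.

Everything here operates on plain float64 arrays so it can be called from
the hot Monte Carlo kernels.  Lengths are in units of the disc diameter
``sigma``; boxes are ``[0, L) x [0, L)`` with periodic boundaries.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def min_image(d: float, L: float) -> float:
    """Minimum-image convention for a single coordinate difference."""
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True)
def pair_dist2_pbc(x1, y1, x2, y2, L):
    dx = min_image(x2 - x1, L)
    dy = min_image(y2 - y1, L)
    return dx * dx + dy * dy


@njit(cache=True, inline="always")
def _orient(ax, ay, bx, by, cx, cy):
    """Sign of the cross product (b-a) x (c-a)."""
    return (bx - ax) * (cy - ay) - (by - ay) * (cx - ax)


@njit(cache=True)
def segments_intersect(p0x, p0y, p1x, p1y, q0x, q0y, q1x, q1y):
    """True if closed segments p0-p1 and q0-q1 intersect (touching counts).

    Grazing contacts (endpoint on the other segment, collinear overlap) are
    reported as intersections: the Monte Carlo acceptance rule treats ties
    conservatively.
    """
    d1 = _orient(q0x, q0y, q1x, q1y, p0x, p0y)
    d2 = _orient(q0x, q0y, q1x, q1y, p1x, p1y)
    d3 = _orient(p0x, p0y, p1x, p1y, q0x, q0y)
    d4 = _orient(p0x, p0y, p1x, p1y, q1x, q1y)
    if ((d1 > 0 and d2 < 0) or (d1 < 0 and d2 > 0)) and (
        (d3 > 0 and d4 < 0) or (d3 < 0 and d4 > 0)
    ):
        return True
    # collinear / endpoint-touching cases
    if d1 == 0.0 and _on_segment(q0x, q0y, q1x, q1y, p0x, p0y):
        return True
    if d2 == 0.0 and _on_segment(q0x, q0y, q1x, q1y, p1x, p1y):
        return True
    if d3 == 0.0 and _on_segment(p0x, p0y, p1x, p1y, q0x, q0y):
        return True
    if d4 == 0.0 and _on_segment(p0x, p0y, p1x, p1y, q1x, q1y):
        return True
    return False


@njit(cache=True, inline="always")
def _on_segment(ax, ay, bx, by, px, py):
    """Assuming p collinear with a-b, is p within the bounding box of a-b?"""
    return (
        min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by)
    )


@njit(cache=True)
def segment_intersection_param(p0x, p0y, p1x, p1y, q0x, q0y, q1x, q1y):
    """Parameter t in [0,1] along p0->p1 of the crossing with q0-q1, or -1.

    Returns -1.0 when the segments do not intersect.  For collinear overlap
    the smallest overlapping parameter is returned (conservative: earliest
    contact).
    """
    rx = p1x - p0x
    ry = p1y - p0y
    sx = q1x - q0x
    sy = q1y - q0y
    denom = rx * sy - ry * sx
    qpx = q0x - p0x
    qpy = q0y - p0y
    if denom == 0.0:
        # parallel; collinear overlap only
        if qpx * ry - qpy * rx != 0.0:
            return -1.0
        rr = rx * rx + ry * ry
        if rr == 0.0:
            return -1.0
        t0 = (qpx * rx + qpy * ry) / rr
        t1 = t0 + (sx * rx + sy * ry) / rr
        lo = min(t0, t1)
        hi = max(t0, t1)
        if hi < 0.0 or lo > 1.0:
            return -1.0
        return max(lo, 0.0)
    t = (qpx * sy - qpy * sx) / denom
    u = (qpx * ry - qpy * rx) / denom
    if 0.0 <= t <= 1.0 and 0.0 <= u <= 1.0:
        return t
    return -1.0


@njit(cache=True)
def point_in_triangle(px, py, ax, ay, bx, by, cx, cy):
    """Closed point-in-triangle test (boundary counts as inside)."""
    d1 = _orient(ax, ay, bx, by, px, py)
    d2 = _orient(bx, by, cx, cy, px, py)
    d3 = _orient(cx, cy, ax, ay, px, py)
    has_neg = (d1 < 0) or (d2 < 0) or (d3 < 0)
    has_pos = (d1 > 0) or (d2 > 0) or (d3 > 0)
    return not (has_neg and has_pos)


# ---------------------------------------------------------------------------
# cell list over obstacle centres (periodic)
# ---------------------------------------------------------------------------

@njit(cache=True)
def build_cell_list(pos, L, cell_width_min):
    """Linked-cell list: returns (head, nxt, ncell, cw).

    ``head[cx, cy]`` is the first particle in the cell (-1 if empty) and
    ``nxt[i]`` chains the rest.  Cell width is >= cell_width_min so a 3x3
    neighbourhood scan covers all centres within one diameter.
    """
    n = pos.shape[0]
    ncell = int(L // cell_width_min)
    if ncell < 3:
        ncell = 3
    cw = L / ncell
    head = -np.ones((ncell, ncell), dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cw)
        cy = int(pos[i, 1] / cw)
        if cx >= ncell:
            cx = ncell - 1
        if cy >= ncell:
            cy = ncell - 1
        nxt[i] = head[cx, cy]
        head[cx, cy] = i
    return head, nxt, ncell, cw


@njit(cache=True)
def any_overlap(x, y, pos, head, nxt, ncell, cw, L, dist2):
    """True if any centre lies within sqrt(dist2) of (x, y), min-image."""
    cx = int(x / cw)
    cy = int(y / cw)
    if cx >= ncell:
        cx = ncell - 1
    if cy >= ncell:
        cy = ncell - 1
    for dx in range(-1, 2):
        for dy in range(-1, 2):
            j = head[(cx + dx) % ncell, (cy + dy) % ncell]
            while j >= 0:
                if pair_dist2_pbc(x, y, pos[j, 0], pos[j, 1], L) < dist2:
                    return True
                j = nxt[j]
    return False
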