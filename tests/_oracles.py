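"""Independent brute-force oracles used to validate the geometric machinery.

Each oracle deliberately avoids the code path it checks: wrapping
detection is re-derived from a pixel flood fill of the accessible void
space, accessible areas from rejection sampling, and channel crossings
from dense sub-stepping with point location.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _accessible_mask(positions, L, sigma, spacing):
    n = int(round(L / spacing))
    mask = np.ones((n, n), dtype=np.uint8)
    r = sigma / spacing
    r2 = r * r
    for k in range(positions.shape[0]):
        cx = positions[k, 0] / spacing
        cy = positions[k, 1] / spacing
        lo_x = int(np.floor(cx - r)) - 1
        hi_x = int(np.ceil(cx + r)) + 1
        lo_y = int(np.floor(cy - r)) - 1
        hi_y = int(np.ceil(cy + r)) + 1
        for i in range(lo_x, hi_x + 1):
            for j in range(lo_y, hi_y + 1):
                dx = i + 0.5 - cx
                dy = j + 0.5 - cy
                if dx * dx + dy * dy < r2:
                    mask[i % n, j % n] = 0
    return mask


@njit(cache=True)
def _flood_wraps(mask):
    """BFS over accessible pixels with unwrapped-offset bookkeeping.

    A component wraps an axis iff a pixel is reached twice with different
    unwrapped offsets along that axis.
    """
    n = mask.shape[0]
    seen = np.zeros((n, n), dtype=np.uint8)
    off = np.zeros((n, n, 2), dtype=np.int32)
    qx = np.empty(n * n, dtype=np.int32)
    qy = np.empty(n * n, dtype=np.int32)
    wrap_x = False
    wrap_y = False
    for sx in range(n):
        for sy in range(n):
            if mask[sx, sy] == 0 or seen[sx, sy]:
                continue
            head = 0
            tail = 0
            qx[tail] = sx
            qy[tail] = sy
            tail += 1
            seen[sx, sy] = 1
            off[sx, sy, 0] = 0
            off[sx, sy, 1] = 0
            while head < tail:
                x = qx[head]
                y = qy[head]
                head += 1
                for d in range(4):
                    if d == 0:
                        nx2, ny2, ox, oy = x + 1, y, 1, 0
                    elif d == 1:
                        nx2, ny2, ox, oy = x - 1, y, -1, 0
                    elif d == 2:
                        nx2, ny2, ox, oy = x, y + 1, 0, 1
                    else:
                        nx2, ny2, ox, oy = x, y - 1, 0, -1
                    wx = nx2 % n
                    wy = ny2 % n
                    if mask[wx, wy] == 0:
                        continue
                    nox = off[x, y, 0] + ox
                    noy = off[x, y, 1] + oy
                    if seen[wx, wy]:
                        if off[wx, wy, 0] != nox:
                            wrap_x = True
                        if off[wx, wy, 1] != noy:
                            wrap_y = True
                    else:
                        seen[wx, wy] = 1
                        off[wx, wy, 0] = nox
                        off[wx, wy, 1] = noy
                        qx[tail] = wx
                        qy[tail] = wy
                        tail += 1
            if wrap_x and wrap_y:
                return wrap_x, wrap_y
    return wrap_x, wrap_y


def grid_percolates(matrix, spacing: float = 0.02) -> bool:
    """Flood-fill oracle: does the tracer-accessible space wrap the torus?"""
    mask = _accessible_mask(matrix.positions, matrix.L, matrix.sigma, spacing)
    wx, wy = _flood_wraps(mask)
    return bool(wx or wy)


def wrapping_with_gap_margin(network, eps: float) -> bool:
    """Wrapping of the pore network with passability tightened to g > eps.

    A pixel grid of spacing h cannot resolve corridors narrower than a few
    h, so the flood-fill answer must lie between the tightened
    (g > ~3h, conservative) and exact (g > 0, liberal) wrapping answers.
    """
    from crowdperc.pores import _wrapping_clusters

    wx, wy = _wrapping_clusters(
        network.n_triangles, network.edge_tri, network.edge_offset,
        network.gaps > eps,
    )
    return bool(wx or wy)


def mc_accessible_area(vertices, sigma: float, n_points: int, rng) -> tuple[float, float]:
    """Rejection-sampling estimate (value, stderr) of a pore's accessible area."""
    verts = np.asarray(vertices, dtype=float)
    a, b, c = verts
    u = rng.random(n_points)
    v = rng.random(n_points)
    flip = u + v > 1
    u[flip] = 1 - u[flip]
    v[flip] = 1 - v[flip]
    pts = a + u[:, None] * (b - a) + v[:, None] * (c - a)
    free = np.ones(n_points, dtype=bool)
    for vert in verts:
        d2 = ((pts - vert) ** 2).sum(axis=1)
        free &= d2 >= sigma**2
    area_tri = 0.5 * abs(
        (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    )
    p = free.mean()
    return area_tri * p, area_tri * np.sqrt(p * (1 - p) / n_points)


def substep_crossings(old, new, network, n_sub: int = 1000) -> set[int]:
    """Channels crossed along old->new, from dense point location.

    Locates the pore containing each sub-point and records the shared
    channel at every pore change; misses grazing contacts by construction,
    so it lower-bounds the exact crossing set.
    """
    old = np.asarray(old, float)
    new = np.asarray(new, float)
    ts = np.linspace(0.0, 1.0, n_sub + 1)
    crossed: set[int] = set()
    prev = network.locate(old % network.L)
    for t in ts[1:]:
        p = old + t * (new - old)
        cur = network.locate(p % network.L)
        if cur != prev:
            shared = set(network.tri_edges[prev]) & set(network.tri_edges[cur])
            crossed.update(shared)
            prev = cur
    return crossed
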