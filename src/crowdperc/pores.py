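"""Delaunay pore networks and continuum percolation of the void space.

The void space of a hard-disc matrix is discretised into *pores* (Delaunay
triangles over the obstacle centres on the torus) connected by *channels*
(triangle edges).  A channel of centre-to-centre length ``l`` has gap
``g = l - 2 sigma`` (the sum of the matrix-disc and tracer diameters is
``2 sigma``): the tracer centre can cross only if ``g > 0``.  A matrix
percolates when the graph of pores joined by passable channels contains a
cluster that wraps the periodic box in at least one axis.

The percolation threshold ``phi_c`` is located by measuring the wrapping
probability P(phi, L), fitting it to
``P = 1/2 [1 + tanh((phi_c(L) - phi)/dphi)]`` and extrapolating the
finite-size thresholds with ``phi_c - phi_c(L) ~ L^(-1/nu)``, ``nu = 4/3``
in 2D.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from numba import njit
from scipy.optimize import curve_fit
from scipy.spatial import Delaunay, cKDTree
from scipy.stats import linregress
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from . import _geometry as geom
from .matrix import ObstacleMatrix, generate_matrix
from .results import ExponentFit


class TessellationError(RuntimeError):
    """The periodic triangulation failed its topological validation."""


@dataclasses.dataclass
class PoreNetwork:
    """Periodic Delaunay tessellation of an obstacle matrix.

    Triangles are *pores*; edges are *channels*.  Each triangle is stored
    once (its canonical copy, the one whose centroid falls in the central
    cell), with explicit per-vertex periodic image shifts so that
    ``tri_coords`` are true Euclidean coordinates (possibly slightly
    outside ``[0, L)``).

    Arrays
    ------
    tri_vertices : (T, 3) int      obstacle indices of each pore's corners
    tri_shifts   : (T, 3, 2) int   periodic image shift of each corner (units of L)
    tri_coords   : (T, 3, 2) float corner coordinates [sigma]
    tri_area     : (T,) float      pore area [sigma^2]
    tri_edges    : (T, 3) int      channel id of side i (opposite corner i)
    edge_tri     : (E, 2) int      the two pores sharing each channel
    edge_side    : (E, 2) int      side index of the channel in each pore
    edge_offset  : (E, 2) int      lattice offset: seen from pore edge_tri[e,0],
                                   the adjacent copy of pore edge_tri[e,1] sits at
                                   its canonical position + offset * L
    edge_length  : (E,) float      centre-to-centre channel length l [sigma]
    gaps         : (E,) float      channel gap g = l - 2 sigma [sigma]
    passable     : (E,) bool       g > 0
    """

    L: float
    sigma: float
    tri_vertices: np.ndarray
    tri_shifts: np.ndarray
    tri_coords: np.ndarray
    tri_area: np.ndarray
    tri_edges: np.ndarray
    edge_tri: np.ndarray
    edge_side: np.ndarray
    edge_offset: np.ndarray
    edge_length: np.ndarray
    gaps: np.ndarray
    passable: np.ndarray

    _centroid_tree: cKDTree | None = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def n_triangles(self) -> int:
        return self.tri_vertices.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_tri.shape[0]

    @property
    def centroids(self) -> np.ndarray:
        return self.tri_coords.mean(axis=1)

    def triangle_gaps(self) -> np.ndarray:
        """(T, 3) gap of each pore's three channels, in side order."""
        return self.gaps[self.tri_edges]

    def accessible_areas(self) -> np.ndarray:
        """(T,) area of each pore reachable by the tracer centre."""
        return np.array(
            [accessible_area(c, self.sigma) for c in self.tri_coords]
        )

    def locate(self, point) -> int:
        """Index of the pore containing a point of the box (periodic)."""
        p = np.asarray(point, dtype=float) % self.L
        if self._centroid_tree is None:
            object.__setattr__(
                self, "_centroid_tree", cKDTree(self.centroids % self.L, boxsize=self.L)
            )
        k = min(12, self.n_triangles)
        _, cand = self._centroid_tree.query(p, k=k)
        for t in np.atleast_1d(cand):
            c = self.centroids[t]
            q = p - self.L * np.round((p - c) / self.L)
            a, b, cc = self.tri_coords[t]
            if geom.point_in_triangle(q[0], q[1], a[0], a[1], b[0], b[1], cc[0], cc[1]):
                return int(t)
        # fall back to a full scan (degenerate boundary cases)
        for t in range(self.n_triangles):
            c = self.centroids[t]
            q = p - self.L * np.round((p - c) / self.L)
            a, b, cc = self.tri_coords[t]
            if geom.point_in_triangle(q[0], q[1], a[0], a[1], b[0], b[1], cc[0], cc[1]):
                return int(t)
        raise RuntimeError(f"point {point} not located in any pore")


def channel_gap(l: float, sigma: float) -> float:
    """Gap g = l - 2 sigma of a channel of centre-to-centre length l.

    ``2 sigma`` is the sum of the matrix-disc and tracer diameters; the
    channel is passable to the tracer centre only when g > 0.  May be
    negative (impassable channel).
    """
    if l <= 0:
        raise ValueError("channel length must be positive")
    return l - 2.0 * sigma


def _replicate(points: np.ndarray, L: float, margin: float):
    """Image copies of boundary points within ``margin`` outside the box."""
    n = points.shape[0]
    coords = [points]
    orig = [np.arange(n)]
    shifts = [np.zeros((n, 2), dtype=np.int64)]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = points + L * np.array([sx, sy], dtype=float)
            mask = (
                (shifted[:, 0] > -margin)
                & (shifted[:, 0] < L + margin)
                & (shifted[:, 1] > -margin)
                & (shifted[:, 1] < L + margin)
            )
            if mask.any():
                coords.append(shifted[mask])
                orig.append(np.nonzero(mask)[0])
                shifts.append(
                    np.tile(np.array([sx, sy], dtype=np.int64), (int(mask.sum()), 1))
                )
    return np.vstack(coords), np.concatenate(orig), np.vstack(shifts)


def tessellate(
    matrix: ObstacleMatrix, margin: float | None = None, _jitter: float = 1e-10
) -> PoreNetwork:
    """Periodic Delaunay tessellation of the obstacle centres.

    Implemented by triangulating the points together with the periodic
    images that fall within a margin band outside the box and keeping the
    triangles whose centroid lies in the central cell.  The margin starts
    at a density-based heuristic and doubles (up to the full 3x3 tiling)
    until the torus topology validates: every channel shared by exactly two
    pores, E = 3T/2, T = 2N, and N - E + T = 0.

    Co-circular degeneracies are broken by a deterministic O(1e-10 sigma)
    jitter keyed on the matrix seed; all geometric quantities inherit a
    perturbation far below any physical tolerance.
    """
    n = matrix.N
    if n < 3:
        raise ValueError("tessellation requires at least 3 obstacles")
    L, sigma = matrix.L, matrix.sigma
    rng = np.random.default_rng([int(matrix.seed) & 0x7FFFFFFF, 0xDE1A])
    jpos = matrix.positions + _jitter * rng.standard_normal((n, 2))

    if margin is None:
        margin = max(6.0 * sigma, 4.0 * L / np.sqrt(n))
    margin = min(margin, L)
    last_err: Exception | None = None
    while True:
        try:
            return _tessellate_once(matrix, jpos, margin)
        except TessellationError as err:  # margin too small: widen and retry
            last_err = err
            if margin >= L:
                raise TessellationError(
                    f"periodic tessellation failed even at full tiling: {last_err}"
                )
            margin = min(2.0 * margin, L)


def _tessellate_once(
    matrix: ObstacleMatrix, jpos: np.ndarray, margin: float
) -> PoreNetwork:
    n = matrix.N
    L, sigma = matrix.L, matrix.sigma
    coords, orig, shifts = _replicate(jpos, L, margin)
    tri = Delaunay(coords)
    simp = tri.simplices
    cent = coords[simp].mean(axis=1)
    keep = (
        (cent[:, 0] >= 0.0) & (cent[:, 0] < L) & (cent[:, 1] >= 0.0) & (cent[:, 1] < L)
    )
    simp = simp[keep]
    T = simp.shape[0]
    if T != 2 * n:
        raise TessellationError(f"kept {T} triangles, expected {2 * n}")

    tri_vertices = orig[simp]
    tri_shifts = shifts[simp]
    # true coordinates from the *unjittered* positions
    tri_coords = matrix.positions[tri_vertices] + L * tri_shifts.astype(float)

    # shoelace areas (counter-clockwise or clockwise; take abs)
    a, b, c = tri_coords[:, 0], tri_coords[:, 1], tri_coords[:, 2]
    tri_area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (b[:, 1] - a[:, 1]) * (c[:, 0] - a[:, 0])
    )

    # canonical edge matching, vectorised over all 3T half-edges: each
    # half-edge gets an orientation-independent integer key; a valid torus
    # triangulation has every key exactly twice
    tri_ids = np.repeat(np.arange(T), 3)
    sides = np.tile(np.arange(3), T)
    i1 = (sides + 1) % 3
    i2 = (sides + 2) % 3
    o1 = tri_vertices[tri_ids, i1].astype(np.int64)
    o2 = tri_vertices[tri_ids, i2].astype(np.int64)
    s1 = tri_shifts[tri_ids, i1]  # (3T, 2)
    s2 = tri_shifts[tri_ids, i2]
    r0 = s2[:, 0] - s1[:, 0]
    r1 = s2[:, 1] - s1[:, 1]
    # orientation: (o1, o2, r0, r1) vs the flipped (o2, o1, -r0, -r1)
    first = (o1 < o2) | (
        (o1 == o2) & ((r0 < -r0) | ((r0 == -r0) & (r1 <= -r1)))
    )
    ka = np.where(first, o1, o2)
    kb = np.where(first, o2, o1)
    kr0 = np.where(first, r0, -r0) + 2  # rel shifts lie in [-2, 2]
    kr1 = np.where(first, r1, -r1) + 2
    frame = np.where(first[:, None], s1, s2)  # shift of the canonical first vertex
    key = ((ka * (n + 1) + kb) * 5 + kr0) * 5 + kr1
    order = np.argsort(key, kind="stable")
    skey = key[order]
    E = 3 * T // 2
    if skey.size != 2 * E or not (
        (skey[0::2] == skey[1::2]).all()
        and (skey[0::2][1:] != skey[0::2][:-1]).all()
    ):
        raise TessellationError("channel not shared by exactly two pores")
    if n - E + T != 0:
        raise TessellationError(f"Euler check failed: N={n} E={E} T={T}")
    h0 = order[0::2]
    h1 = order[1::2]
    edge_tri = np.stack([tri_ids[h0], tri_ids[h1]], axis=1)
    edge_side = np.stack([sides[h0], sides[h1]], axis=1)
    edge_offset = frame[h0] - frame[h1]
    tri_edges = -np.ones((T, 3), dtype=np.int64)
    e_ids = np.arange(E)
    tri_edges[edge_tri[:, 0], edge_side[:, 0]] = e_ids
    tri_edges[edge_tri[:, 1], edge_side[:, 1]] = e_ids
    if (tri_edges < 0).any():
        raise TessellationError("incomplete pore-channel incidence")

    # channel lengths from the frame of the first incident pore
    t0 = edge_tri[:, 0]
    s0 = edge_side[:, 0]
    p1 = tri_coords[t0, (s0 + 1) % 3]
    p2 = tri_coords[t0, (s0 + 2) % 3]
    edge_length = np.hypot(p1[:, 0] - p2[:, 0], p1[:, 1] - p2[:, 1])
    gaps = edge_length - 2.0 * sigma

    return PoreNetwork(
        L=L,
        sigma=sigma,
        tri_vertices=tri_vertices,
        tri_shifts=tri_shifts,
        tri_coords=tri_coords,
        tri_area=tri_area,
        tri_edges=tri_edges,
        edge_tri=edge_tri,
        edge_side=edge_side,
        edge_offset=edge_offset,
        edge_length=edge_length,
        gaps=gaps,
        passable=gaps > 0.0,
    )


def accessible_area(vertices, sigma: float) -> float:
    """Pore area reachable by the tracer centre.

    Triangle area minus its intersection with the three exclusion discs of
    radius ``sigma`` centred at the corners, computed by exact polygon-disc
    clipping (the discs may mutually overlap inside small pores).  When
    each disc meets the triangle only in the circular sector at its own
    corner this reduces to ``A_tri - pi sigma^2 / 2``.  Clamped at 0.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.shape != (3, 2):
        raise ValueError("vertices must be three 2D points")
    poly = Polygon(verts)
    if poly.area == 0.0:
        return 0.0
    discs = unary_union([Point(v).buffer(sigma, quad_segs=256) for v in verts])
    return float(max(poly.difference(discs).area, 0.0))


def gap_distribution(
    network: PoreNetwork, bins: int | np.ndarray = 50
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalised density rho(g) of the channel gap over g >= 0.

    Channels with negative gap are excluded from the density and reported
    separately as the impassable fraction.  Returns
    ``(bin_centres, density, impassable_fraction)``.
    """
    if network.n_edges == 0:
        raise ValueError("empty network")
    g = network.gaps
    pos = g[g > 0]
    impassable_fraction = 1.0 - pos.size / g.size
    if pos.size == 0:
        raise ValueError("no passable channels to bin")
    density, edges = np.histogram(pos, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density, impassable_fraction


# ---------------------------------------------------------------------------
# wrapping-cluster detection (union-find with displacement bookkeeping)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _uf_find(parent, disp, x):
    r = x
    while parent[r] != r:
        r = parent[r]
    cur = x
    dx = 0
    dy = 0
    while parent[cur] != cur:
        dx += disp[cur, 0]
        dy += disp[cur, 1]
        cur = parent[cur]
    # path compression with displacement rebasing
    cur = x
    rx, ry = dx, dy
    while parent[cur] != cur:
        nxt = parent[cur]
        odx, ody = disp[cur, 0], disp[cur, 1]
        parent[cur] = r
        disp[cur, 0] = rx
        disp[cur, 1] = ry
        rx -= odx
        ry -= ody
        cur = nxt
    return r, dx, dy


@njit(cache=True)
def _wrapping_clusters(n_tri, edge_tri, edge_offset, passable):
    parent = np.arange(n_tri)
    rank = np.zeros(n_tri, dtype=np.int64)
    disp = np.zeros((n_tri, 2), dtype=np.int64)
    wrap_x = False
    wrap_y = False
    for e in range(edge_tri.shape[0]):
        if not passable[e]:
            continue
        a = edge_tri[e, 0]
        b = edge_tri[e, 1]
        kx = edge_offset[e, 0]
        ky = edge_offset[e, 1]
        ra, dax, day = _uf_find(parent, disp, a)
        rb, dbx, dby = _uf_find(parent, disp, b)
        if ra == rb:
            # position of b implied through this channel vs recorded position
            if dbx != dax + kx:
                wrap_x = True
            if dby != day + ky:
                wrap_y = True
        else:
            if rank[ra] < rank[rb]:
                # attach ra under rb: disp so that pos(b) = pos(a) + k still holds
                parent[ra] = rb
                disp[ra, 0] = dbx - kx - dax
                disp[ra, 1] = dby - ky - day
            else:
                parent[rb] = ra
                disp[rb, 0] = dax + kx - dbx
                disp[rb, 1] = day + ky - dby
                if rank[ra] == rank[rb]:
                    rank[ra] += 1
        if wrap_x and wrap_y:
            break
    return wrap_x, wrap_y


@njit(cache=True)
def _cluster_labels(n_tri, edge_tri, edge_offset, passable):
    parent = np.arange(n_tri)
    rank = np.zeros(n_tri, dtype=np.int64)
    disp = np.zeros((n_tri, 2), dtype=np.int64)
    wrap_flag = np.zeros((n_tri, 2), dtype=np.uint8)  # indexed by root at event time
    for e in range(edge_tri.shape[0]):
        if not passable[e]:
            continue
        a = edge_tri[e, 0]
        b = edge_tri[e, 1]
        kx = edge_offset[e, 0]
        ky = edge_offset[e, 1]
        ra, dax, day = _uf_find(parent, disp, a)
        rb, dbx, dby = _uf_find(parent, disp, b)
        if ra == rb:
            if dbx != dax + kx:
                wrap_flag[ra, 0] = 1
            if dby != day + ky:
                wrap_flag[ra, 1] = 1
        else:
            if rank[ra] < rank[rb]:
                parent[ra] = rb
                disp[ra, 0] = dbx - kx - dax
                disp[ra, 1] = dby - ky - day
            else:
                parent[rb] = ra
                disp[rb, 0] = dax + kx - dbx
                disp[rb, 1] = day + ky - dby
                if rank[ra] == rank[rb]:
                    rank[ra] += 1
    labels = np.empty(n_tri, dtype=np.int64)
    wraps = np.zeros((n_tri, 2), dtype=np.uint8)  # per final root
    for i in range(n_tri):
        r, _, _ = _uf_find(parent, disp, i)
        labels[i] = r
        if wrap_flag[i, 0]:
            wraps[r, 0] = 1
        if wrap_flag[i, 1]:
            wraps[r, 1] = 1
    return labels, wraps


def cluster_labels(network: PoreNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected clusters of pores joined by passable channels.

    Returns ``(labels, wrap_x, wrap_y)``: a cluster id per pore and, per
    pore, whether its cluster wraps the torus in x / in y.
    """
    labels, wraps = _cluster_labels(
        network.n_triangles, network.edge_tri, network.edge_offset, network.passable
    )
    return labels, wraps[labels, 0].astype(bool), wraps[labels, 1].astype(bool)


def place_tracers_on_wrapping_cluster(
    matrix: ObstacleMatrix,
    network: PoreNetwork,
    n_tracers: int,
    seed: int,
    max_attempts: int = 10**5,
) -> np.ndarray:
    """Tracer placement restricted to pores of a wrapping cluster.

    Same non-overlap rules as :func:`crowdperc.matrix.place_tracers`, plus
    the requirement that each tracer's starting pore belong to a cluster
    that wraps the torus in at least one axis.  Useful below phi_c to
    exclude the tracers trapped in finite pockets from MSD averages.
    """
    from .matrix import place_tracers

    _, wx, wy = cluster_labels(network)
    on_cluster = wx | wy
    if not on_cluster.any():
        raise ValueError("no wrapping cluster exists in this matrix")
    L, sigma = matrix.L, matrix.sigma
    out = np.empty((n_tracers, 2))
    placed = 0
    for k in range(max_attempts):
        cand = place_tracers(matrix, 1, seed=int(seed) + 7919 * k)[0]
        if not on_cluster[network.locate(cand)]:
            continue
        if placed:
            d = out[:placed] - cand
            d -= L * np.round(d / L)
            if ((d**2).sum(axis=1) < sigma**2).any():
                continue
        out[placed] = cand
        placed += 1
        if placed == n_tracers:
            return out
    raise RuntimeError(
        f"placed only {placed}/{n_tracers} tracers on the wrapping cluster"
    )


def has_wrapping_cluster(network: PoreNetwork) -> tuple[bool, bool]:
    """Whether some cluster of pores joined by passable channels wraps the
    torus in x and in y.

    Union-find over pores with per-channel lattice-offset bookkeeping: a
    cycle whose accumulated offset is non-zero in an axis wraps that axis.
    """
    wx, wy = _wrapping_clusters(
        network.n_triangles, network.edge_tri, network.edge_offset, network.passable
    )
    return bool(wx), bool(wy)


def percolates(network: PoreNetwork, mode: str = "either") -> bool:
    """Percolation criterion: wrapping in at least one axis (default).

    ``mode`` may be "either", "both", "x" or "y".
    """
    wx, wy = has_wrapping_cluster(network)
    if mode == "either":
        return wx or wy
    if mode == "both":
        return wx and wy
    if mode == "x":
        return wx
    if mode == "y":
        return wy
    raise ValueError(f"unknown percolation mode {mode!r}")


# ---------------------------------------------------------------------------
# percolation probability and phi_c
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PercolationCurve:
    """Monte Carlo wrapping probability P(phi) at fixed box size L."""

    L: float
    phi_values: np.ndarray
    P: np.ndarray
    stderr: np.ndarray
    n_configs: int

    def __post_init__(self) -> None:
        self.phi_values = np.asarray(self.phi_values, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if not ((self.P >= 0) & (self.P <= 1)).all():
            raise ValueError("P must be probabilities")


def _config_seeds(seed: int, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    return (ss.generate_state(n) & 0x7FFFFFFF).astype(np.int64)


def percolation_probability(
    phi: float, L: float, n_configs: int, seed: int, mode: str = "either"
) -> tuple[float, float]:
    """Fraction of independent RSA configurations with a wrapping cluster.

    Returns (P, binomial standard error).
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    seeds = _config_seeds(seed, n_configs)
    hits = 0
    for s in seeds:
        m = generate_matrix(phi, L, int(s))
        hits += percolates(tessellate(m), mode=mode)
    p = hits / n_configs
    return p, float(np.sqrt(p * (1 - p) / n_configs))


def percolation_curve(
    phi_values, L: float, n_configs: int, seed: int, mode: str = "either"
) -> PercolationCurve:
    """P(phi) over a grid of area fractions at fixed L."""
    phi_values = np.asarray(phi_values, dtype=float)
    P = np.empty_like(phi_values)
    err = np.empty_like(phi_values)
    for i, phi in enumerate(phi_values):
        P[i], err[i] = percolation_probability(
            phi, L, n_configs, int(seed) + 7919 * i, mode=mode
        )
    return PercolationCurve(L=L, phi_values=phi_values, P=P, stderr=err, n_configs=n_configs)


def _tanh_form(phi, phi_c, dphi):
    return 0.5 * (1.0 + np.tanh((phi_c - phi) / dphi))


def fit_percolation_curve(curve: PercolationCurve) -> ExponentFit:
    """Fit P(phi) to 1/2 [1 + tanh((phi_c(L) - phi)/dphi)].

    The fitted curve passes through 1/2 at phi_c(L) by construction.
    Requires >= 4 points bracketing the transition (max P > 0.8 and
    min P < 0.2).
    """
    phi, P = curve.phi_values, curve.P
    if phi.size < 4:
        raise ValueError("need at least 4 phi points")
    if P.max() <= 0.8 or P.min() >= 0.2:
        raise ValueError("P(phi) does not bracket the transition (0.8 -> 0.2)")
    i0 = int(np.argmin(np.abs(P - 0.5)))
    p0 = (phi[i0], max((phi.max() - phi.min()) / 6.0, 1e-4))
    popt, pcov = curve_fit(_tanh_form, phi, P, p0=p0, maxfev=10000)
    phi_c_L, dphi = popt
    err = float(np.sqrt(np.abs(pcov[0, 0])))
    return ExponentFit(
        name="phi_c_L",
        value=float(phi_c_L),
        stderr=err,
        fit_window=(float(phi.min()), float(phi.max())),
        metadata={
            "delta_phi": float(abs(dphi)),
            "L": float(curve.L),
            "n_configs": int(curve.n_configs),
        },
    )


def extrapolate_phi_c(fits: dict, nu: float = 4.0 / 3.0) -> ExponentFit:
    """Extrapolate finite-size thresholds to L -> infinity.

    ``fits`` maps L -> phi_c(L) (floats or :class:`ExponentFit`).  Linear
    fit of phi_c(L) against L^(-1/nu); the intercept is phi_c.
    """
    if len(fits) < 3:
        raise ValueError("need at least 3 distinct L for the extrapolation")
    Ls = np.array(sorted(fits), dtype=float)
    y = np.array(
        [
            fits[L].value if isinstance(fits[L], ExponentFit) else float(fits[L])
            for L in sorted(fits)
        ]
    )
    x = Ls ** (-1.0 / nu)
    res = linregress(x, y)
    return ExponentFit(
        name="phi_c",
        value=float(res.intercept),
        stderr=float(res.intercept_stderr),
        fit_window=(float(Ls.min()), float(Ls.max())),
        metadata={"nu": nu, "slope": float(res.slope), "L_values": Ls.tolist()},
    )


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def save_network(network: PoreNetwork, path) -> None:
    """Serialise a pore network to JSON (lossless round-trip)."""
    payload = {
        "L": network.L,
        "sigma": network.sigma,
        "tri_vertices": network.tri_vertices.tolist(),
        "tri_shifts": network.tri_shifts.tolist(),
        "tri_area": network.tri_area.tolist(),
        "tri_edges": network.tri_edges.tolist(),
        "edge_tri": network.edge_tri.tolist(),
        "edge_side": network.edge_side.tolist(),
        "edge_offset": network.edge_offset.tolist(),
        "edge_length": network.edge_length.tolist(),
        "gaps": network.gaps.tolist(),
        "tri_coords": network.tri_coords.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_network(path) -> PoreNetwork:
    d = json.loads(Path(path).read_text())
    gaps = np.asarray(d["gaps"], dtype=float)
    return PoreNetwork(
        L=float(d["L"]),
        sigma=float(d["sigma"]),
        tri_vertices=np.asarray(d["tri_vertices"], dtype=np.int64),
        tri_shifts=np.asarray(d["tri_shifts"], dtype=np.int64),
        tri_coords=np.asarray(d["tri_coords"], dtype=float),
        tri_area=np.asarray(d["tri_area"], dtype=float),
        tri_edges=np.asarray(d["tri_edges"], dtype=np.int64),
        edge_tri=np.asarray(d["edge_tri"], dtype=np.int64),
        edge_side=np.asarray(d["edge_side"], dtype=np.int64),
        edge_offset=np.asarray(d["edge_offset"], dtype=np.int64),
        edge_length=np.asarray(d["edge_length"], dtype=float),
        gaps=gaps,
        passable=gaps > 0.0,
    )
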