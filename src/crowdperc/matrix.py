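"""Quenched random hard-disc matrices (the obstacle media).

The medium is a random sequential adsorption (RSA) configuration of
non-overlapping hard discs of diameter ``sigma`` (= 1, the unit of length)
in a periodic square box of side ``L``.  Discs are inserted one at a time at
uniform random positions; a trial position overlapping a previously placed
disc is discarded and redrawn.  The area fraction is ``phi = pi N sigma^2 /
(4 L^2)``.

The matrices generated here are the quenched disorder every downstream
stage (pore tessellation, percolation, tracer dynamics, rate analysis)
consumes.
"""
from __future__ import annotations

import dataclasses
import math
import re
from pathlib import Path

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from . import _geometry as geom


class SaturationError(RuntimeError):
    """RSA insertion failed: the target area fraction is too high."""


class PlacementError(RuntimeError):
    """Tracer placement failed within the attempt cap."""


@dataclasses.dataclass
class ObstacleMatrix:
    """A quenched configuration of non-overlapping discs on the torus.

    positions : (N, 2) float array, centres in [0, L) x [0, L), units of sigma
    L         : box side [sigma]
    sigma     : disc diameter (tracer and matrix discs share it; default 1)
    seed      : seed the configuration was generated from
    """

    positions: np.ndarray
    L: float
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    @property
    def phi(self) -> float:
        return area_fraction(self.N, self.L, self.sigma)


def area_fraction(N: int, L: float, sigma: float = 1.0) -> float:
    """Area fraction phi = pi N sigma^2 / (4 L^2) of N discs in an L x L box."""
    if L <= 0:
        raise ValueError("L must be positive")
    return math.pi * N * sigma**2 / (4.0 * L**2)


def n_discs_for(phi: float, L: float, sigma: float = 1.0) -> int:
    """Disc count whose area fraction is closest to the target phi."""
    return int(round(4.0 * phi * L**2 / (math.pi * sigma**2)))


@njit(cache=True)
def _rsa_kernel(n, L, sigma, seed, max_attempts):
    np.random.seed(seed)
    pos = np.empty((n, 2), dtype=np.float64)
    ncell = int(L // sigma)
    if ncell < 3:
        ncell = 3
    cw = L / ncell
    head = -np.ones((ncell, ncell), dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    sigma2 = sigma * sigma
    for i in range(n):
        placed = False
        for _ in range(max_attempts):
            x = np.random.random() * L
            y = np.random.random() * L
            if not geom.any_overlap(x, y, pos[:i], head, nxt, ncell, cw, L, sigma2):
                pos[i, 0] = x
                pos[i, 1] = y
                cx = min(int(x / cw), ncell - 1)
                cy = min(int(y / cw), ncell - 1)
                nxt[i] = head[cx, cy]
                head[cx, cy] = i
                placed = True
                break
        if not placed:
            return pos, i  # saturated after i discs
    return pos, n


def generate_matrix(
    phi: float,
    L: float,
    seed: int,
    sigma: float = 1.0,
    max_attempts: int = 10**6,
) -> ObstacleMatrix:
    """Generate an RSA configuration at area fraction ``phi``.

    The number of discs is ``round(4 phi L^2 / (pi sigma^2))``.  Identical
    ``(phi, L, seed)`` give identical output.  Raises :class:`SaturationError`
    if a disc cannot be placed within ``max_attempts`` trials (phi too close
    to the RSA jamming density, ~0.547 for discs).
    """
    if not 0 <= phi < 1:
        raise ValueError("phi must be in [0, 1)")
    if L < 10 * sigma:
        raise ValueError("L must be at least 10 sigma")
    n = n_discs_for(phi, L, sigma)
    if n == 0:
        return ObstacleMatrix(np.empty((0, 2)), L=L, sigma=sigma, seed=seed)
    pos, placed = _rsa_kernel(n, L, sigma, int(seed) & 0x7FFFFFFF, max_attempts)
    if placed < n:
        raise SaturationError(
            f"RSA saturated after {placed}/{n} discs at phi={phi:.4g} "
            f"(attempt cap {max_attempts})"
        )
    return ObstacleMatrix(pos, L=L, sigma=sigma, seed=seed)


def place_tracers(
    matrix: ObstacleMatrix,
    n_tracers: int,
    seed: int,
    max_attempts: int = 10**6,
) -> np.ndarray:
    """Place tracer discs at random non-overlapping positions.

    At placement, each tracer centre must be >= sigma (minimum image) from
    every matrix centre and from every previously placed tracer centre.
    Tracer-tracer interactions are switched off afterwards, so only the
    initial condition enforces mutual exclusion.
    """
    if n_tracers < 1:
        raise ValueError("n_tracers must be positive")
    rng = np.random.default_rng(seed)
    L, sigma = matrix.L, matrix.sigma
    tree = cKDTree(matrix.positions, boxsize=L) if matrix.N else None
    out = np.empty((n_tracers, 2))
    placed = 0
    for _ in range(max_attempts):
        p = rng.random(2) * L
        if tree is not None and tree.query(p, k=1)[0] < sigma:
            continue
        ok = True
        for j in range(placed):
            dx = p[0] - out[j, 0]
            dy = p[1] - out[j, 1]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            if dx * dx + dy * dy < sigma * sigma:
                ok = False
                break
        if ok:
            out[placed] = p
            placed += 1
            if placed == n_tracers:
                return out
    raise PlacementError(
        f"placed only {placed}/{n_tracers} tracers within {max_attempts} attempts"
    )


def radial_distribution(
    matrix: ObstacleMatrix, dr: float, r_max: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pair correlation function g(r) of the matrix centres.

    Standard estimator: pair counts in shells [r, r+dr) normalised by the
    ideal-gas expectation N rho pi [(r+dr)^2 - r^2] / 2 per shell (each pair
    counted once).  Requires ``r_max <= L/2`` for minimum-image validity.
    Returns (bin centres, g).
    """
    if r_max > matrix.L / 2:
        raise ValueError("r_max must not exceed L/2 (minimum image ambiguous)")
    if dr <= 0:
        raise ValueError("dr must be positive")
    n = matrix.N
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    centers = 0.5 * (edges[:-1] + edges[1:])
    if n < 2:
        return centers, np.zeros_like(centers)
    tree = cKDTree(matrix.positions, boxsize=matrix.L)
    pairs = tree.query_pairs(r=float(edges[-1]), output_type="ndarray")
    d = matrix.positions[pairs[:, 0]] - matrix.positions[pairs[:, 1]]
    d -= matrix.L * np.round(d / matrix.L)
    dist = np.hypot(d[:, 0], d[:, 1])
    counts, _ = np.histogram(dist, bins=edges)
    rho = n / matrix.L**2
    shell_area = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    expected = 0.5 * n * rho * shell_area  # pairs counted once
    g = np.where(expected > 0, counts / expected, 0.0)
    return centers, g


# ---------------------------------------------------------------------------
# validation and plain-text IO
# ---------------------------------------------------------------------------

def check_no_overlap(matrix: ObstacleMatrix) -> bool:
    """Verify the hard-core constraint on every pair (min-image distance >= sigma).

    Brute-force O(N^2) scan up to N = 5000, cell-list (KDTree) scan above.
    """
    pos, L, sigma = matrix.positions, matrix.L, matrix.sigma
    n = matrix.N
    if n < 2:
        return True
    if n <= 5000:
        d = pos[:, None, :] - pos[None, :, :]
        d -= L * np.round(d / L)
        dist2 = (d**2).sum(-1)
        np.fill_diagonal(dist2, np.inf)
        return bool(dist2.min() >= sigma**2 * (1 - 1e-12))
    tree = cKDTree(pos, boxsize=L)
    pairs = tree.query_pairs(r=sigma * (1 - 1e-12))
    return len(pairs) == 0


def save_matrix(matrix: ObstacleMatrix, path) -> None:
    """Write a matrix as CSV with a metadata header; lossless round-trip."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# L={float(matrix.L)!r} sigma={float(matrix.sigma)!r} "
            f"phi={float(matrix.phi)!r} seed={matrix.seed}\n"
        )
        fh.write("x,y\n")
        for x, y in matrix.positions:
            fh.write(f"{float(x)!r},{float(y)!r}\n")


def load_matrix(path) -> ObstacleMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        m = re.match(
            r"#\s*L=(\S+)\s+sigma=(\S+)\s+phi=(\S+)\s+seed=(\S+)", header
        )
        if not m:
            raise ValueError(f"malformed matrix header: {header!r}")
        L, sigma, _phi, seed = m.groups()
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    if data.size == 0:
        data = np.empty((0, 2))
    return ObstacleMatrix(data, L=float(L), sigma=float(sigma), seed=int(seed))
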