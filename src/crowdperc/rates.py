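"""Pore-level transition rates: transition-state theory vs direct simulation.

Under the local-equilibrium approximation, transition-state theory (TST)
gives the escape rate through a channel of gap ``g`` out of a pore of
accessible area ``A`` as ``W_TST ~ g / A`` (ratio of the transition-state
and reactant partition functions, both ideal for hard discs), with a
dynamical prefactor comparable to the free diffusivity ``D0``.  The
per-channel escape probability is ``P_TST = g_i / sum_i g_i``.

The numerical counterpart starts a tracer uniformly over the accessible
region of a pore, evolves it with the dynamic MC rules, and records the
first passage out of the pore: the mean first-passage time ``tau_MFPT``
and exit-side frequencies ``P_num = N_i / N_trial`` give
``W_num = P_num / (2 tau_MFPT)``.

At small step size Delta the tracer equilibrates inside the pore before
escaping and ``W_num ~ D0 W_TST``; at large Delta the local-equilibrium
approximation fails, small-gap channels are selected even less often than
TST predicts, and the rate distribution ``rho(W_num)`` develops a
power-law singularity ``~ W^-alpha`` at small W.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from numba import njit
from scipy.spatial import cKDTree

from . import _geometry as geom
from .matrix import ObstacleMatrix
from .mc import _edge_segments, free_diffusivity
from .pores import PoreNetwork, accessible_area
from .results import ExponentFit


class ClosedPoreError(ValueError):
    """The pore has no passable channel: no escape is possible."""


def tst_rate(g: float, A: float) -> float:
    """TST escape rate W_TST = max(g, 0)/A through one channel.

    Impassable channels (g <= 0) carry zero rate.  For comparison with
    numerically measured rates multiply by the dynamical prefactor D0.
    """
    if A <= 0:
        raise ValueError("accessible area must be positive")
    return max(g, 0.0) / A


def p_tst(gaps) -> np.ndarray:
    """TST escape probabilities P_TST = g_i / sum g_i over a pore's 3 sides.

    Negative gaps are clamped to zero.  Raises :class:`ClosedPoreError`
    when no side is passable.
    """
    g = np.maximum(np.asarray(gaps, dtype=float), 0.0)
    if g.shape != (3,):
        raise ValueError("a pore has exactly three channels")
    s = g.sum()
    if s <= 0:
        raise ClosedPoreError("all channel gaps are non-positive")
    return g / s


def numerical_rate(P_num: float, tau_MFPT: float) -> float:
    """W_num = P_num / (2 tau_MFPT)."""
    if tau_MFPT <= 0:
        raise ValueError("tau_MFPT must be positive")
    return P_num / (2.0 * tau_MFPT)


# ---------------------------------------------------------------------------
# first-passage simulation
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fp_kernel(tri, obst, segs, sigma2, delta, n_trials, step_cap, start_cap, seed):
    """First-passage trials out of one pore.

    tri  : (3, 2) triangle corner coordinates (local Euclidean frame)
    obst : (M, 2) obstacle centres near the pore (images resolved)
    segs : (K, 4) impassable channel segments near the pore
    """
    np.random.seed(seed)
    ax, ay = tri[0, 0], tri[0, 1]
    bx, by = tri[1, 0], tri[1, 1]
    cx, cy = tri[2, 0], tri[2, 1]
    counts = np.zeros(3, dtype=np.int64)
    total_t = 0.0
    n_escaped = 0
    censored = 0
    M = obst.shape[0]
    K = segs.shape[0]
    for _ in range(n_trials):
        # start uniform over the accessible region (rejection sampling)
        px = 0.0
        py = 0.0
        placed = False
        for _ in range(start_cap):
            u = np.random.random()
            v = np.random.random()
            if u + v > 1.0:
                u = 1.0 - u
                v = 1.0 - v
            qx = ax + u * (bx - ax) + v * (cx - ax)
            qy = ay + u * (by - ay) + v * (cy - ay)
            free = True
            for j in range(M):
                dx = qx - obst[j, 0]
                dy = qy - obst[j, 1]
                if dx * dx + dy * dy < sigma2:
                    free = False
                    break
            if free:
                px = qx
                py = qy
                placed = True
                break
        if not placed:
            censored += 1
            continue
        escaped = False
        step = 0
        while step < step_cap:
            step += 1
            dx = (2.0 * np.random.random() - 1.0) * delta
            dy = (2.0 * np.random.random() - 1.0) * delta
            nx = px + dx
            ny = py + dy
            bad = False
            for j in range(M):
                ddx = nx - obst[j, 0]
                ddy = ny - obst[j, 1]
                if ddx * ddx + ddy * ddy < sigma2:
                    bad = True
                    break
            if bad:
                continue
            if geom.point_in_triangle(nx, ny, ax, ay, bx, by, cx, cy):
                # segment between two interior points of a convex pore cannot
                # cross any channel: accept without the crossing scan
                px = nx
                py = ny
            else:
                crossed = False
                for s in range(K):
                    if geom.segments_intersect(
                        px, py, nx, ny,
                        segs[s, 0], segs[s, 1], segs[s, 2], segs[s, 3],
                    ):
                        crossed = True
                        break
                if crossed:
                    continue
                # exit side: first triangle edge crossed, in parametric order
                tmin = 2.0
                side = -1
                t0 = geom.segment_intersection_param(px, py, nx, ny, bx, by, cx, cy)
                if 0.0 <= t0 < tmin:
                    tmin = t0
                    side = 0
                t1 = geom.segment_intersection_param(px, py, nx, ny, cx, cy, ax, ay)
                if 0.0 <= t1 < tmin:
                    tmin = t1
                    side = 1
                t2 = geom.segment_intersection_param(px, py, nx, ny, ax, ay, bx, by)
                if 0.0 <= t2 < tmin:
                    side = 2
                if side < 0:
                    # grazing numerical tie: reject conservatively
                    continue
                counts[side] += 1
                total_t += step
                n_escaped += 1
                escaped = True
                break
        if not escaped:
            censored += 1
    return total_t, n_escaped, counts, censored


@dataclasses.dataclass
class _LocalEnv:
    tri: np.ndarray
    obst: np.ndarray
    segs: np.ndarray


def _local_environment(
    pore: int,
    matrix: ObstacleMatrix,
    network: PoreNetwork,
    delta: float,
    obst_tree: cKDTree | None = None,
    seg_mid: np.ndarray | None = None,
    seg_tree: cKDTree | None = None,
    seg_base: np.ndarray | None = None,
) -> _LocalEnv:
    """Obstacles and impassable channels within reach of one pore's trials."""
    L = matrix.L
    tri = network.tri_coords[pore]
    cen = tri.mean(axis=0)
    r_tri = float(np.max(np.hypot(tri[:, 0] - cen[0], tri[:, 1] - cen[1])))
    R = r_tri + matrix.sigma + delta * math.sqrt(2.0) + 0.25
    if R >= L / 2:
        raise ValueError("pore reach exceeds L/2; box too small for this pore")
    if obst_tree is None:
        obst_tree = cKDTree(matrix.positions, boxsize=L)
    idx = obst_tree.query_ball_point(cen % L, R)
    disp = matrix.positions[idx] - (cen % L)
    disp -= L * np.round(disp / L)
    obst = cen + disp
    # nearest first: overlap rejections (the common case) break early
    order = np.argsort((disp**2).sum(axis=1))
    obst = obst[order]
    if seg_base is None:
        imp = np.nonzero(~network.passable)[0]
        seg_base = _edge_segments(network, imp)
        seg_mid = 0.5 * (seg_base[:, :2] + seg_base[:, 2:])
        seg_tree = cKDTree(seg_mid % L, boxsize=L) if seg_base.shape[0] else None
    if seg_tree is not None:
        half_len = 0.5 * np.hypot(
            seg_base[:, 2] - seg_base[:, 0], seg_base[:, 3] - seg_base[:, 1]
        )
        reach = R + float(half_len.max() if half_len.size else 0.0)
        reach = min(reach, L / 2 * 0.999)
        sidx = seg_tree.query_ball_point(cen % L, reach)
        mdisp = (seg_mid[sidx] % L) - (cen % L)
        mdisp -= L * np.round(mdisp / L)
        mids = cen + mdisp
        shift = mids - seg_mid[sidx]
        segs = seg_base[sidx] + np.hstack([shift, shift])
    else:
        segs = np.empty((0, 4))
    return _LocalEnv(tri=np.ascontiguousarray(tri), obst=np.ascontiguousarray(obst),
                     segs=np.ascontiguousarray(segs))


def first_passage(
    pore: int,
    matrix: ObstacleMatrix,
    network: PoreNetwork,
    delta: float,
    n_trials: int,
    seed: int,
    step_cap: int = 10**8,
) -> tuple[float, np.ndarray, int]:
    """Mean first-passage time and exit-side frequencies for one pore.

    Each trial starts the tracer uniformly over the pore's accessible
    region (the equilibrium measure TST presupposes) and evolves it with
    the dynamic MC acceptance rules until the first accepted move whose
    endpoint leaves the starting triangle; the exit side is the first
    starting-triangle edge crossed by that move.  Time advances one unit
    per attempt (a single tracer).  Trials not escaping within
    ``step_cap`` attempts are censored and excluded from the mean.

    Returns ``(tau_MFPT, P_num three-vector = N_i / n_trials, n_censored)``.
    """
    gaps = network.triangle_gaps()[pore]
    if (gaps <= 0).all():
        raise ClosedPoreError(f"pore {pore} has no passable channel")
    env = _local_environment(pore, matrix, network, delta)
    total_t, n_esc, counts, censored = _fp_kernel(
        env.tri, env.obst, env.segs, matrix.sigma**2, delta,
        n_trials, step_cap, 100000, int(seed) & 0x7FFFFFFF,
    )
    if n_esc == 0:
        raise RuntimeError(f"no escapes from pore {pore} within step cap")
    tau = total_t / n_esc
    p_num = counts / n_trials
    return float(tau), p_num, int(censored)


def rate_table(
    matrix: ObstacleMatrix,
    network: PoreNetwork,
    delta: float,
    n_trials: int,
    seed: int,
    pores: np.ndarray | None = None,
    step_cap: int = 10**7,
) -> pd.DataFrame:
    """Per-channel TST and numerical rates over (a subset of) the pores.

    Pores with no passable channel or with vanishing accessible area are
    skipped.  Returns one row per (pore, side) with columns
    ``pore_id, side, g, A, W_TST, P_TST, tau_MFPT, P_num, W_num,
    n_trials, censored``.
    """
    all_gaps = network.triangle_gaps()
    if pores is None:
        pores = np.arange(network.n_triangles)
    obst_tree = cKDTree(matrix.positions, boxsize=matrix.L)
    imp = np.nonzero(~network.passable)[0]
    seg_base = _edge_segments(network, imp)
    seg_mid = 0.5 * (seg_base[:, :2] + seg_base[:, 2:])
    seg_tree = cKDTree(seg_mid % matrix.L, boxsize=matrix.L) if seg_base.shape[0] else None
    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    pore_seeds = (ss.generate_state(len(pores)) & 0x7FFFFFFF).astype(int)
    rows = []
    for pi, pore in enumerate(pores):
        gaps = all_gaps[pore]
        if (gaps <= 0).all():
            continue
        A = accessible_area(network.tri_coords[pore], matrix.sigma)
        if A <= 1e-9:
            continue
        env = _local_environment(
            pore, matrix, network, delta,
            obst_tree=obst_tree, seg_mid=seg_mid, seg_tree=seg_tree,
            seg_base=seg_base,
        )
        total_t, n_esc, counts, censored = _fp_kernel(
            env.tri, env.obst, env.segs, matrix.sigma**2, delta,
            n_trials, step_cap, 100000, int(pore_seeds[pi]),
        )
        if n_esc == 0:
            continue
        tau = total_t / n_esc
        ptst = p_tst(gaps)
        pnum = counts / n_trials
        for side in range(3):
            rows.append(
                {
                    "pore_id": int(pore),
                    "side": side,
                    "g": float(gaps[side]),
                    "A": float(A),
                    "W_TST": tst_rate(float(gaps[side]), A),
                    "P_TST": float(ptst[side]),
                    "tau_MFPT": float(tau),
                    "P_num": float(pnum[side]),
                    "W_num": numerical_rate(float(pnum[side]), float(tau)),
                    "n_trials": int(n_trials),
                    "censored": int(censored),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rate distributions and the singularity exponent alpha
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RateHistogram:
    """Logarithmically binned normalised density of positive rates."""

    centers: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    edges: np.ndarray
    n_zero: int


def rate_distribution(
    rates, bins_per_decade: int = 10, min_positive: int = 100
) -> RateHistogram:
    """Log-binned density rho(W) over the positive rates.

    The density is normalised so it integrates to 1 over the positive
    support; zero rates are excluded and reported via ``n_zero``.
    """
    rates = np.asarray(rates, dtype=float)
    pos = rates[rates > 0]
    n_zero = int(rates.size - pos.size)
    if pos.size == 0:
        raise ValueError("all rates are zero")
    if pos.size < min_positive:
        raise ValueError(f"need >= {min_positive} positive rates, got {pos.size}")
    lo = math.floor(np.log10(pos.min()) * bins_per_decade) / bins_per_decade
    hi = math.ceil(np.log10(pos.max()) * bins_per_decade) / bins_per_decade
    if hi <= lo:
        hi = lo + 1.0 / bins_per_decade
    edges = 10.0 ** np.arange(lo, hi + 0.5 / bins_per_decade, 1.0 / bins_per_decade)
    counts, _ = np.histogram(pos, bins=edges)
    widths = np.diff(edges)
    density = counts / (pos.size * widths)
    centers = np.sqrt(edges[:-1] * edges[1:])
    return RateHistogram(
        centers=centers, density=density, counts=counts, edges=edges, n_zero=n_zero
    )


def fit_alpha(
    rho: RateHistogram,
    window_decades: float = 1.5,
    min_count: int = 10,
    min_bins: int = 5,
) -> ExponentFit:
    """Singularity exponent from rho(W) ~ W^-alpha at small W.

    Weighted least squares of log rho against log W over the lowest
    ``window_decades`` decades in which *every* bin holds at least
    ``min_count`` entries (weights ~ counts, the Poisson variance of log
    density).  Requiring a contiguous well-occupied block avoids the
    selection bias of admitting isolated low-count bins that happened to
    fluctuate upward.
    """
    n = rho.centers.size
    sel = None
    for i in range(n):
        if rho.counts[i] < min_count:
            continue
        block = (rho.centers <= rho.centers[i] * 10**window_decades) & (
            np.arange(n) >= i
        )
        if (rho.counts[block] >= min_count).all() and block.sum() >= min_bins:
            sel = block
            break
    if sel is None:
        raise ValueError(
            f"no contiguous small-W window of >= {min_bins} bins with >= "
            f"{min_count} counts each"
        )
    x = np.log10(rho.centers[sel])
    y = np.log10(rho.density[sel])
    w = rho.counts[sel].astype(float)
    W = w.sum()
    xbar = (w * x).sum() / W
    ybar = (w * y).sum() / W
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    resid = y - (ybar + slope * (x - xbar))
    dof = max(int(sel.sum()) - 2, 1)
    s2 = (w * resid**2).sum() / dof
    stderr = float(np.sqrt(s2 / sxx))
    return ExponentFit(
        name="alpha",
        value=float(-slope),
        stderr=stderr,
        fit_window=(float(10 ** x.min()), float(10 ** x.max())),
        metadata={"n_bins": int(sel.sum()), "window_decades": window_decades},
    )


def ratio_distribution(
    p_num, p_tst_vals, bins: int = 60, r_max: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised density of P_num / P_TST over paired channels.

    Pairs with P_TST = 0 are dropped.  The linear grid covers at least
    [0, 3].  Returns (bin centres, density).
    """
    p_num = np.asarray(p_num, dtype=float)
    p_tst_vals = np.asarray(p_tst_vals, dtype=float)
    if p_num.shape != p_tst_vals.shape:
        raise ValueError("P_num and P_TST must be paired")
    mask = p_tst_vals > 0
    ratio = p_num[mask] / p_tst_vals[mask]
    if ratio.size == 0:
        raise ValueError("no channels with positive P_TST")
    top = max(3.0, float(ratio.max())) if r_max is None else r_max
    density, edges = np.histogram(ratio, bins=bins, range=(0.0, top), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density


def tail_mass_outside(p_num, p_tst_vals, lo: float = 0.4, hi: float = 1.6) -> float:
    """Fraction of channels whose P_num/P_TST falls outside [lo, hi]."""
    p_num = np.asarray(p_num, dtype=float)
    p_tst_vals = np.asarray(p_tst_vals, dtype=float)
    mask = p_tst_vals > 0
    ratio = p_num[mask] / p_tst_vals[mask]
    return float(((ratio < lo) | (ratio > hi)).mean())


def tst_comparison(table: pd.DataFrame, delta: float) -> pd.DataFrame:
    """Per-channel comparison of W_num against D0 * W_TST.

    Adds the Kramers-motivated prefactor D0 = Delta^2/6 to the TST rate
    and the decimal log-ratio; rows with W_num = 0 or W_TST = 0 are
    dropped (no ratio defined).
    """
    d0 = free_diffusivity(delta)
    sub = table[(table.W_num > 0) & (table.W_TST > 0)].copy()
    sub["D0_W_TST"] = d0 * sub["W_TST"]
    sub["log10_ratio"] = np.log10(sub["W_num"] / sub["D0_W_TST"])
    return sub
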