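"""Dynamic Monte Carlo for hard-disc tracers in a quenched matrix.

Each trial move picks a tracer at random and proposes a displacement whose
x and y components are independently uniform on ``[-Delta, Delta]``.  The
move is accepted iff

1. the proposed position does not overlap any matrix disc
   (minimum-image centre distance >= sigma), and
2. the displacement segment does not cross any *impassable* channel of the
   pore network (channels with gap ``g = l - 2 sigma <= 0``): a tracer may
   not squeeze between two obstacles whose surface-to-surface clearance is
   below its own diameter, however large the jump.

Rule 2 forbids the geometric tunnelling that large Delta would otherwise
allow and keeps the percolation threshold independent of Delta.  Crossing
any number of *passable* channels in a single jump is allowed.

Time is measured in Monte Carlo sweeps: one unit of ``t`` elapses per
``N_tracer`` attempted moves, so a free tracer has diffusion coefficient
``D0 = Delta^2 / 6`` (``<delta_x^2 + delta_y^2> / 4`` per unit time with
``<delta_x^2> = Delta^2/3``).
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
from numba import njit

from . import _geometry as geom
from .matrix import ObstacleMatrix, place_tracers
from .pores import PoreNetwork
from .results import ExponentFit


class NoDiffusiveWindowError(RuntimeError):
    """The MSD curve never reaches the diffusive (slope ~ 1) regime."""


def free_diffusivity(delta: float) -> float:
    """Analytic free-space diffusion coefficient D0 = Delta^2 / 6."""
    return delta**2 / 6.0


@dataclasses.dataclass
class SimulationParams:
    """Dynamic MC run parameters.

    delta          : maximum per-axis displacement Delta [sigma]
    t_max          : run length in MC time units (sweeps)
    n_tracers      : tracers per matrix configuration
    sampling_times : increasing times in (0, t_max] at which positions are stored
    seed           : RNG seed
    """

    delta: float
    t_max: float
    n_tracers: int = 10
    sampling_times: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.sampling_times is None:
            self.sampling_times = log_times(self.t_max)
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if (self.sampling_times <= 0).any() or (
            self.sampling_times > self.t_max + 1e-9
        ).any():
            raise ValueError("sampling_times must lie in (0, t_max]")
        if not (np.diff(self.sampling_times) > 0).all():
            raise ValueError("sampling_times must be strictly increasing")


def log_times(t_max: float, per_decade: int = 12, t_min: float = 1.0) -> np.ndarray:
    """Log-spaced sampling times from t_min to t_max."""
    n = max(int(per_decade * math.log10(t_max / t_min)) + 1, 2)
    t = np.geomspace(t_min, t_max, n)
    return np.unique(np.round(t, 6))


@dataclasses.dataclass
class TrajectoryEnsemble:
    """Unwrapped tracer positions sampled at fixed times for one matrix."""

    times: np.ndarray       # (n_t,)
    positions: np.ndarray   # (n_t, n_tracers, 2), unwrapped
    start: np.ndarray       # (n_tracers, 2)
    phi: float
    delta: float
    L: float
    seed: int


@dataclasses.dataclass
class MSDCurve:
    """Ensemble-averaged mean-squared displacement <(Dr)^2(t)>."""

    times: np.ndarray
    msd: np.ndarray
    phi: float
    delta: float
    n_samples: int
    L: float = float("nan")

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        if (self.msd < 0).any():
            raise ValueError("msd must be non-negative")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")


def trial_move(rng: np.random.Generator, delta: float) -> np.ndarray:
    """One proposed displacement: components iid uniform on [-delta, delta]."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return rng.uniform(-delta, delta, 2)


# ---------------------------------------------------------------------------
# impassable-channel spatial grid (built once per network + delta)
# ---------------------------------------------------------------------------

def _edge_segments(network: PoreNetwork, which: np.ndarray) -> np.ndarray:
    """(K, 4) segments (x1,y1,x2,y2) of the selected channels, canonical frame."""
    t0 = network.edge_tri[which, 0]
    s0 = network.edge_side[which, 0]
    p1 = network.tri_coords[t0, (s0 + 1) % 3]
    p2 = network.tri_coords[t0, (s0 + 2) % 3]
    return np.hstack([p1, p2])


@dataclasses.dataclass
class EdgeGrid:
    """Uniform grid over impassable channel segments in an expanded frame.

    The domain ``[-margin, L+margin]^2`` holds the canonical segments plus
    any periodic images intersecting it, so trial segments starting from a
    wrapped position never need wrapping themselves (their reach beyond the
    box is at most ``delta*sqrt(2) <= margin``).
    """

    segments: np.ndarray     # (K, 4)
    cell_start: np.ndarray   # CSR offsets, (ncell*ncell + 1,)
    cell_items: np.ndarray
    ncell: int
    cw: float
    x0: float

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


def build_edge_grid(network: PoreNetwork, margin: float, cell_width: float = 1.0) -> EdgeGrid:
    L = network.L
    base = _edge_segments(network, np.nonzero(~network.passable)[0])
    segs = []
    lo, hi = -margin, L + margin
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            s = base + np.array([sx * L, sy * L, sx * L, sy * L])
            if s.size == 0:
                continue
            bx1 = np.minimum(s[:, 0], s[:, 2])
            bx2 = np.maximum(s[:, 0], s[:, 2])
            by1 = np.minimum(s[:, 1], s[:, 3])
            by2 = np.maximum(s[:, 1], s[:, 3])
            keep = (bx2 >= lo) & (bx1 <= hi) & (by2 >= lo) & (by1 <= hi)
            if keep.any():
                segs.append(s[keep])
    segments = np.vstack(segs) if segs else np.empty((0, 4))
    ncell = max(int(np.ceil((hi - lo) / cell_width)), 1)
    cw = (hi - lo) / ncell
    buckets: list[list[int]] = [[] for _ in range(ncell * ncell)]
    for k in range(segments.shape[0]):
        x1, y1, x2, y2 = segments[k]
        cx1 = int(np.clip((min(x1, x2) - lo) / cw, 0, ncell - 1))
        cx2 = int(np.clip((max(x1, x2) - lo) / cw, 0, ncell - 1))
        cy1 = int(np.clip((min(y1, y2) - lo) / cw, 0, ncell - 1))
        cy2 = int(np.clip((max(y1, y2) - lo) / cw, 0, ncell - 1))
        for cx in range(cx1, cx2 + 1):
            for cy in range(cy1, cy2 + 1):
                buckets[cx * ncell + cy].append(k)
    cell_start = np.zeros(ncell * ncell + 1, dtype=np.int64)
    for i, b in enumerate(buckets):
        cell_start[i + 1] = cell_start[i] + len(b)
    cell_items = np.empty(cell_start[-1], dtype=np.int64)
    for i, b in enumerate(buckets):
        cell_items[cell_start[i] : cell_start[i + 1]] = b
    return EdgeGrid(
        segments=segments,
        cell_start=cell_start,
        cell_items=cell_items,
        ncell=ncell,
        cw=cw,
        x0=lo,
    )


@njit(cache=True)
def _crosses_any(ox, oy, nx, ny, segments, cell_start, cell_items, ncell, cw, x0):
    bx1 = min(ox, nx)
    bx2 = max(ox, nx)
    by1 = min(oy, ny)
    by2 = max(oy, ny)
    cx1 = int((bx1 - x0) / cw)
    cx2 = int((bx2 - x0) / cw)
    cy1 = int((by1 - x0) / cw)
    cy2 = int((by2 - x0) / cw)
    if cx1 < 0:
        cx1 = 0
    if cy1 < 0:
        cy1 = 0
    if cx2 >= ncell:
        cx2 = ncell - 1
    if cy2 >= ncell:
        cy2 = ncell - 1
    for cx in range(cx1, cx2 + 1):
        for cy in range(cy1, cy2 + 1):
            c = cx * ncell + cy
            for idx in range(cell_start[c], cell_start[c + 1]):
                k = cell_items[idx]
                if geom.segments_intersect(
                    ox, oy, nx, ny,
                    segments[k, 0], segments[k, 1], segments[k, 2], segments[k, 3],
                ):
                    return True
    return False


# ---------------------------------------------------------------------------
# python-level acceptance rules (reference implementation, used in tests
# and for single moves; the production path is the numba kernel below)
# ---------------------------------------------------------------------------

def crossing_check(old, new, network: PoreNetwork) -> list[tuple[int, float, bool]]:
    """Channels crossed by the segment old -> new, in parametric order.

    ``new - old`` must be a direct (unwrapped) displacement no longer than
    L/2.  Returns ``[(edge_index, t, passable), ...]`` sorted by the
    crossing parameter t along the segment.
    """
    old = np.asarray(old, dtype=float)
    new = np.asarray(new, dtype=float)
    d = new - old
    if np.hypot(d[0], d[1]) > network.L / 2:
        raise ValueError("segment longer than L/2: periodic image ambiguous")
    L = network.L
    all_segs = _edge_segments(network, np.arange(network.n_edges))
    hits = []
    for e in range(network.n_edges):
        x1, y1, x2, y2 = all_segs[e]
        # test the edge image nearest to the segment midpoint
        mx, my = (old + new) / 2
        emx, emy = (x1 + x2) / 2, (y1 + y2) / 2
        for sx in (-1, 0, 1):
            for sy in (-1, 0, 1):
                ox_ = sx * L + round((mx - emx) / L) * L
                oy_ = sy * L + round((my - emy) / L) * L
                t = geom.segment_intersection_param(
                    old[0], old[1], new[0], new[1],
                    x1 + ox_, y1 + oy_, x2 + ox_, y2 + oy_,
                )
                if t >= 0:
                    hits.append((e, float(t), bool(network.passable[e])))
    hits.sort(key=lambda h: h[1])
    # deduplicate repeated detections of the same edge
    seen = set()
    out = []
    for e, t, p in hits:
        if e not in seen:
            seen.add(e)
            out.append((e, t, p))
    return out


def accept_move(old, proposed, matrix: ObstacleMatrix, network: PoreNetwork) -> bool:
    """Metropolis acceptance of a tracer displacement (hard constraints only).

    Rejects on obstacle overlap at the proposed position or on crossing any
    impassable channel along the way; otherwise accepts.
    """
    old = np.asarray(old, dtype=float)
    proposed = np.asarray(proposed, dtype=float)
    if matrix.N:
        d = matrix.positions - (proposed % matrix.L)
        d -= matrix.L * np.round(d / matrix.L)
        if ((d**2).sum(axis=1) < matrix.sigma**2).any():
            return False
    for _, _, passable in crossing_check(old, proposed, network):
        if not passable:
            return False
    return True


# ---------------------------------------------------------------------------
# production kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _mc_kernel(
    start, obst, head, nxt, ncell, cw, L, sigma2, delta,
    segments, cell_start, cell_items, gncell, gcw, gx0,
    n_attempts, sample_attempts, seed,
):
    np.random.seed(seed)
    nt = start.shape[0]
    wrapped = np.empty_like(start)
    unwrapped = np.empty_like(start)
    for i in range(nt):
        wrapped[i, 0] = start[i, 0] % L
        wrapped[i, 1] = start[i, 1] % L
        unwrapped[i, 0] = start[i, 0]
        unwrapped[i, 1] = start[i, 1]
    nsamp = sample_attempts.shape[0]
    out = np.empty((nsamp, nt, 2))
    si = 0
    have_obst = obst.shape[0] > 0
    have_seg = segments.shape[0] > 0
    for att in range(1, n_attempts + 1):
        k = np.random.randint(0, nt)
        dx = (2.0 * np.random.random() - 1.0) * delta
        dy = (2.0 * np.random.random() - 1.0) * delta
        ox = wrapped[k, 0]
        oy = wrapped[k, 1]
        nx = ox + dx
        ny = oy + dy
        nxw = nx % L
        nyw = ny % L
        ok = True
        if have_obst and geom.any_overlap(
            nxw, nyw, obst, head, nxt, ncell, cw, L, sigma2
        ):
            ok = False
        if ok and have_seg and _crosses_any(
            ox, oy, nx, ny, segments, cell_start, cell_items, gncell, gcw, gx0
        ):
            ok = False
        if ok:
            wrapped[k, 0] = nxw
            wrapped[k, 1] = nyw
            unwrapped[k, 0] += dx
            unwrapped[k, 1] += dy
        while si < nsamp and sample_attempts[si] == att:
            for i in range(nt):
                out[si, i, 0] = unwrapped[i, 0]
                out[si, i, 1] = unwrapped[i, 1]
            si += 1
    return out


_EMPTY_GRID = None


def _empty_grid() -> EdgeGrid:
    global _EMPTY_GRID
    if _EMPTY_GRID is None:
        _EMPTY_GRID = EdgeGrid(
            segments=np.empty((0, 4)),
            cell_start=np.zeros(2, dtype=np.int64),
            cell_items=np.empty(0, dtype=np.int64),
            ncell=1,
            cw=1.0,
            x0=0.0,
        )
    return _EMPTY_GRID


def run_simulation(
    matrix: ObstacleMatrix,
    network: PoreNetwork | None,
    params: SimulationParams,
    tracers: np.ndarray | None = None,
    edge_grid: EdgeGrid | None = None,
) -> TrajectoryEnsemble:
    """Evolve tracers in one quenched matrix; returns sampled unwrapped paths.

    ``network`` may be None only for an empty matrix (free diffusion).
    Tracers default to fresh non-overlapping random placements drawn from
    ``params.seed``.  Deterministic under fixed seeds.
    """
    L = matrix.L
    if tracers is None:
        if matrix.N:
            tracers = place_tracers(matrix, params.n_tracers, seed=params.seed)
        else:
            rng = np.random.default_rng(params.seed)
            tracers = rng.random((params.n_tracers, 2)) * L
    tracers = np.ascontiguousarray(tracers, dtype=np.float64)
    if edge_grid is None:
        if network is not None and (~network.passable).any():
            edge_grid = build_edge_grid(
                network, margin=params.delta * math.sqrt(2.0) + 0.1
            )
        else:
            edge_grid = _empty_grid()
    if matrix.N:
        head, nxt, ncell, cw = geom.build_cell_list(matrix.positions, L, matrix.sigma)
    else:
        head = -np.ones((3, 3), dtype=np.int64)
        nxt = np.empty(0, dtype=np.int64)
        ncell, cw = 3, L / 3
    nt = tracers.shape[0]
    sample_attempts = np.unique(
        np.maximum(np.round(params.sampling_times * nt).astype(np.int64), 1)
    )
    n_attempts = int(sample_attempts[-1])
    pos = _mc_kernel(
        tracers, matrix.positions, head, nxt, ncell, cw, L,
        matrix.sigma**2, params.delta,
        edge_grid.segments, edge_grid.cell_start, edge_grid.cell_items,
        edge_grid.ncell, edge_grid.cw, edge_grid.x0,
        n_attempts, sample_attempts,
        int(params.seed) & 0x7FFFFFFF,
    )
    return TrajectoryEnsemble(
        times=sample_attempts / nt,
        positions=pos,
        start=tracers,
        phi=matrix.phi,
        delta=params.delta,
        L=L,
        seed=params.seed,
    )


def msd(ensembles: list[TrajectoryEnsemble]) -> MSDCurve:
    """Average <|r(t) - r(0)|^2> over tracers and matrix configurations.

    All ensembles must share the same sampling times (t = 0 is the single
    origin; no sliding-window averaging).
    """
    if not ensembles:
        raise ValueError("need at least one trajectory ensemble")
    times = ensembles[0].times
    total = np.zeros(times.shape[0])
    n = 0
    for ens in ensembles:
        if not np.array_equal(ens.times, times):
            raise ValueError("ensembles have mismatched sampling times")
        disp = ens.positions - ens.start[None, :, :]
        total += (disp**2).sum(axis=2).sum(axis=1)
        n += ens.positions.shape[1]
    return MSDCurve(
        times=times,
        msd=total / n,
        phi=ensembles[0].phi,
        delta=ensembles[0].delta,
        n_samples=n,
        L=ensembles[0].L,
    )


def msd_sliding(
    ensembles: list[TrajectoryEnsemble],
    n_lags: int = 48,
    max_lag_frac: float = 0.5,
) -> MSDCurve:
    """Origin-averaged MSD over uniformly sampled trajectories.

    Requires uniformly spaced sampling times; every stored frame serves as
    a time origin, which suppresses the tail noise of the single-origin
    estimator at the cost of correlated averages.  Lags run from one frame
    up to ``max_lag_frac`` of the run (so each lag retains many origins).
    """
    if not ensembles:
        raise ValueError("need at least one trajectory ensemble")
    times = ensembles[0].times
    dt = times[-1] / times.size
    # sampling times are quantised to whole attempts, so allow sub-sweep slack
    if not np.allclose(times, dt * np.arange(1, times.size + 1), rtol=1e-3, atol=0.75):
        raise ValueError("msd_sliding requires uniform sampling from t = dt")
    nf = times.size + 1  # start frame at t = 0 included
    max_lag = max(int((nf - 1) * max_lag_frac), 1)
    lags = np.unique(np.geomspace(1, max_lag, n_lags).astype(int))
    total = np.zeros(lags.size)
    count = np.zeros(lags.size)
    n = 0
    for ens in ensembles:
        if not np.array_equal(ens.times, times):
            raise ValueError("ensembles have mismatched sampling times")
        frames = np.concatenate([ens.start[None, :, :], ens.positions], axis=0)
        n += frames.shape[1]
        for i, lag in enumerate(lags):
            d = frames[lag:] - frames[:-lag]
            total[i] += (d**2).sum(axis=2).sum()
            count[i] += d.shape[0] * d.shape[1]
    return MSDCurve(
        times=lags * dt,
        msd=total / count,
        phi=ensembles[0].phi,
        delta=ensembles[0].delta,
        n_samples=n,
        L=ensembles[0].L,
    )


def _run_ensembles(
    phi: float,
    L: float,
    delta: float,
    t_max: float,
    n_configs: int,
    n_tracers: int,
    seed: int,
    sampling_times: np.ndarray,
) -> list[TrajectoryEnsemble]:
    from .matrix import generate_matrix
    from .pores import tessellate

    ss = np.random.SeedSequence(int(seed) & 0x7FFFFFFF)
    seeds = (ss.generate_state(2 * n_configs) & 0x7FFFFFFF).astype(int)
    ensembles = []
    for c in range(n_configs):
        m = generate_matrix(phi, L, seeds[2 * c])
        net = tessellate(m) if m.N >= 3 else None
        params = SimulationParams(
            delta=delta,
            t_max=t_max,
            n_tracers=n_tracers,
            sampling_times=sampling_times,
            seed=int(seeds[2 * c + 1]),
        )
        ensembles.append(run_simulation(m, net, params))
    return ensembles


def msd_experiment(
    phi: float,
    L: float,
    delta: float,
    t_max: float,
    n_configs: int,
    n_tracers: int,
    seed: int,
    sampling_times: np.ndarray | None = None,
    sliding: bool = False,
    n_frames: int = 512,
) -> MSDCurve:
    """MSD averaged over ``n_configs`` independent quenched matrices.

    ``sliding=False`` (default): log-spaced sampling, single t = 0 origin.
    ``sliding=True``: uniform sampling with ``n_frames`` stored frames and
    origin-averaged lags (preferred for extracting D at modest ensemble
    sizes).
    """
    if sliding:
        sampling_times = np.linspace(t_max / n_frames, t_max, n_frames)
    elif sampling_times is None:
        sampling_times = log_times(t_max)
    ensembles = _run_ensembles(
        phi, L, delta, t_max, n_configs, n_tracers, seed, sampling_times
    )
    return msd_sliding(ensembles) if sliding else msd(ensembles)


def diffusion_coefficient(
    curve: MSDCurve,
    slope_window: tuple[float, float] = (0.90, 1.05),
    min_decades: float = 0.5,
) -> ExponentFit:
    """Long-time D from the Einstein relation D = <(Dr)^2>/(4t).

    The diffusive window is the latest-ending, longest stretch of the
    curve whose log-log regression slope lies within ``slope_window`` and
    that spans at least ``min_decades``; D is the mean of msd/(4t) over
    the window.  The lower slope bound of 0.90 accommodates the slow
    (near-logarithmic) approach to diffusion of the 2D Lorentz gas at
    moderate box sizes; at phi = 0 the measured slope is 1 and the band is
    irrelevant.
    Raises :class:`NoDiffusiveWindowError` if no such window exists
    (sub-diffusive curve, phi >= phi_c or run too short).
    """
    mask = (curve.msd > 0) & (curve.times > 0)
    t = curve.times[mask]
    m = curve.msd[mask]
    if t.size < 6:
        raise NoDiffusiveWindowError("too few points with positive MSD")
    logt = np.log10(t)
    logm = np.log10(m)
    # final window whose *regression* slope lies in the acceptance band:
    # point-local slopes are dominated by sampling noise, a window fit is
    # not, and the very largest lags (fewest independent origins) may be
    # excluded, so candidate windows may end before the last point
    start = None
    end = None
    last_slope = float("nan")
    for j in range(t.size, 5, -1):
        for i in range(0, j - 5):
            if logt[j - 1] - logt[i] < min_decades:
                break
            s = np.polyfit(logt[i:j], logm[i:j], 1)[0]
            if slope_window[0] <= s <= slope_window[1]:
                start, end, last_slope = i, j, s
                break
        if start is not None:
            break
    if start is None:
        j = t.size
        tail = np.polyfit(logt[max(j - 8, 0):j], logm[max(j - 8, 0):j], 1)[0]
        raise NoDiffusiveWindowError(
            f"no diffusive window: tail slope {tail:.3f} outside "
            f"[{slope_window[0]}, {slope_window[1]}]"
        )
    dvals = m[start:end] / (4.0 * t[start:end])
    D = float(np.mean(dvals))
    stderr = float(np.std(dvals) / np.sqrt(end - start))
    return ExponentFit(
        name="D",
        value=D,
        stderr=stderr,
        fit_window=(float(t[start]), float(t[end - 1])),
        metadata={
            "phi": curve.phi,
            "delta": curve.delta,
            "n_samples": curve.n_samples,
            "n_points": int(end - start),
            "slope": float(last_slope),
        },
    )


def measure_diffusivity(
    phi: float,
    L: float,
    delta: float,
    t_max: float,
    n_configs: int,
    n_tracers: int,
    seed: int,
    max_doublings: int = 2,
) -> ExponentFit:
    """D(phi) with adaptive run extension.

    Runs an origin-averaged MSD experiment and extracts D; if no diffusive
    window has opened by ``t_max`` (slow relaxation for an unlucky quench),
    the run length is doubled up to ``max_doublings`` times before the
    failure propagates.
    """
    last: NoDiffusiveWindowError | None = None
    for attempt in range(max_doublings + 1):
        curve = msd_experiment(
            phi=phi, L=L, delta=delta, t_max=t_max * 2**attempt,
            n_configs=n_configs, n_tracers=n_tracers, seed=seed, sliding=True,
        )
        try:
            return diffusion_coefficient(curve)
        except NoDiffusiveWindowError as err:
            last = err
    raise last


# ---------------------------------------------------------------------------
# plain-text IO
# ---------------------------------------------------------------------------

def save_msd(curve: MSDCurve, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(
            f"# phi={float(curve.phi)!r} delta={float(curve.delta)!r} "
            f"L={float(curve.L)!r} n_samples={curve.n_samples}\n"
        )
        fh.write("t,msd,n_samples\n")
        for t, m in zip(curve.times, curve.msd):
            fh.write(f"{float(t)!r},{float(m)!r},{curve.n_samples}\n")


def load_msd(path) -> MSDCurve:
    import re

    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        m = re.match(
            r"#\s*phi=(\S+)\s+delta=(\S+)\s+L=(\S+)\s+n_samples=(\S+)", header
        )
        if not m:
            raise ValueError(f"malformed MSD header: {header!r}")
        phi, delta, L, n_samples = m.groups()
        data = np.loadtxt(fh, delimiter=",", skiprows=1, ndmin=2)
    return MSDCurve(
        times=data[:, 0],
        msd=data[:, 1],
        phi=float(phi),
        delta=float(delta),
        n_samples=int(n_samples),
        L=float(L),
    )
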