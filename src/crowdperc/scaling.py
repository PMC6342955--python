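"""Critical exponents of tracer diffusion near the percolation threshold.

The long-time diffusion coefficient vanishes as ``D ~ (phi_c - phi)^mu``.
On 2D lattices ``mu = mu_latt = 1.31`` is universal; in the continuum it
can exceed that value when the distribution of pore-to-pore transition
rates develops a power-law singularity ``rho(W) ~ W^-alpha``, in which
case renormalisation-group theory gives
``mu = max(mu_latt, (d-2) nu + 1/(1-alpha))``.

At criticality the MSD obeys the dynamic scaling form

    <(Dr)^2(t)> ~ t^(2/z) f((phi_c - phi) t^(1/(2 nu + mu - beta))),

with ``z = (2 nu - beta + mu)/(nu - beta/2)`` and the 2D percolation
constants ``nu = 4/3``, ``beta = 5/36``; curves at different phi should
collapse when rescaled accordingly.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from scipy.stats import linregress

from .mc import MSDCurve
from .results import ExponentFit


@dataclasses.dataclass
class CriticalConstants:
    """2D percolation constants and the lattice dynamic exponent."""

    nu: float = 4.0 / 3.0
    beta: float = 5.0 / 36.0
    mu_latt: float = 1.31
    d: int = 2
    phi_c: float = 0.2125

    def __post_init__(self) -> None:
        if min(self.nu, self.beta, self.mu_latt, self.phi_c) <= 0:
            raise ValueError("constants must be positive")
        if self.d != 2:
            raise ValueError("only d = 2 is supported")


def fit_mu(
    D_values: dict[float, float | tuple[float, float]],
    phi_c: float,
) -> ExponentFit:
    """Fit D ~ (phi_c - phi)^mu with phi_c held fixed.

    ``D_values`` maps phi -> D or phi -> (D, stderr_D).  Weighted least
    squares of log D against log(phi_c - phi); the slope is mu.  phi_c is
    *not* co-fitted: it is determined independently from the percolation
    stage, and mu / phi_c co-fits are badly conditioned.
    """
    phis = np.array(sorted(D_values))
    if phis.size < 4:
        raise ValueError("need at least 4 phi points below phi_c")
    if (phis >= phi_c).any():
        raise ValueError("all phi must be below phi_c")
    vals = [D_values[p] for p in sorted(D_values)]
    D = np.array([v[0] if isinstance(v, (tuple, list)) else float(v) for v in vals])
    errs = np.array(
        [v[1] if isinstance(v, (tuple, list)) else 0.0 for v in vals]
    )
    if (D <= 0).any():
        raise ValueError("all D must be positive")
    x = np.log(phi_c - phis)
    y = np.log(D)
    if (errs > 0).all():
        w = (D / errs) ** 2  # var(log D) ~ (err/D)^2
    else:
        w = np.ones_like(D)
    W = np.sum(w)
    xbar = np.sum(w * x) / W
    ybar = np.sum(w * y) / W
    sxx = np.sum(w * (x - xbar) ** 2)
    slope = np.sum(w * (x - xbar) * (y - ybar)) / sxx
    resid = y - (ybar + slope * (x - xbar))
    dof = max(phis.size - 2, 1)
    s2 = np.sum(w * resid**2) / dof
    stderr = float(np.sqrt(s2 / sxx))
    return ExponentFit(
        name="mu",
        value=float(slope),
        stderr=stderr,
        fit_window=(float(phis.min()), float(phis.max())),
        metadata={"phi_c": float(phi_c), "n_points": int(phis.size)},
    )


def dynamic_z(mu: float, constants: CriticalConstants | None = None) -> float:
    """Dynamic exponent z = (2 nu - beta + mu)/(nu - beta/2); MSD ~ t^(2/z)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    c = constants or CriticalConstants()
    return (2 * c.nu - c.beta + mu) / (c.nu - c.beta / 2)


def mu_rg(alpha: float, constants: CriticalConstants | None = None) -> float:
    """RG prediction mu = max(mu_latt, (d-2) nu + 1/(1-alpha)).

    In 2D this is max(mu_latt, 1/(1-alpha)); a singularity exponent
    alpha >= 1 would make the rate distribution non-normalisable.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    c = constants or CriticalConstants()
    return max(c.mu_latt, (c.d - 2) * c.nu + 1.0 / (1.0 - alpha))


def scaling_collapse(
    curves: list[MSDCurve],
    phi_c: float,
    mu: float,
    constants: CriticalConstants | None = None,
    beta_sign: int = -1,
    n_grid: int = 60,
) -> tuple[list[tuple[np.ndarray, np.ndarray, float]], float]:
    """Rescale MSD curves onto the critical scaling form and score the collapse.

    Each curve becomes ``x = t (phi_c - phi)^(2 nu + mu - beta)``,
    ``y = msd / t^(2/z)``.  ``beta_sign=+1`` flips the sign of beta in the
    collapse exponent (exposed because the two appearances of the form in
    the source literature disagree; the default follows the scaling
    relation as derived).  The quality score is the mean squared spread of
    log y between curves over their common log-x support: 0 for a perfect
    collapse, larger is worse.

    Returns ``([(x, y, phi), ...], score)``.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 curves below phi_c")
    deltas = {c.delta for c in curves}
    if len(deltas) != 1:
        raise ValueError(f"curves must share delta, got {sorted(deltas)}")
    c = constants or CriticalConstants()
    expo = 2 * c.nu + mu + beta_sign * c.beta
    z = dynamic_z(mu, c)
    rescaled = []
    for curve in curves:
        eps = phi_c - curve.phi
        if eps <= 0:
            raise ValueError("all curves must have phi < phi_c")
        mask = curve.msd > 0
        x = curve.times[mask] * eps**expo
        y = curve.msd[mask] / curve.times[mask] ** (2.0 / z)
        rescaled.append((x, y, curve.phi))
    lo = max(x.min() for x, _, _ in rescaled)
    hi = min(x.max() for x, _, _ in rescaled)
    if not lo < hi:
        raise ValueError("curves share no common support after rescaling")
    grid = np.linspace(np.log10(lo), np.log10(hi), n_grid)
    logys = np.empty((len(rescaled), n_grid))
    for i, (x, y, _) in enumerate(rescaled):
        logys[i] = np.interp(grid, np.log10(x), np.log10(y))
    score = float(np.mean(np.var(logys, axis=0)))
    return rescaled, score


def fit_D_of_phi(
    msd_curves: dict[float, MSDCurve],
) -> dict[float, tuple[float, float]]:
    """Extract D(phi) from MSD curves; returns phi -> (D, stderr)."""
    from .mc import diffusion_coefficient

    out = {}
    for phi, curve in msd_curves.items():
        fit = diffusion_coefficient(curve)
        out[phi] = (fit.value, fit.stderr)
    return out
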