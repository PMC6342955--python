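"""End-to-end experiment orchestration.

Sequences the study's stages — percolation threshold, Delta-sweep of the
diffusion exponent mu, and the transition-rate / singularity-exponent
analysis — with explicit seeds, cached intermediates and a JSON report.

Two scale presets exist: ``desk`` (the default; box sizes and sample
counts sized for a single CPU) and ``paper`` (the full study conditions:
L up to 2000, up to 1000 percolation configurations, 300 matrix
configurations per (phi, Delta), N_trial = 8000 first-passage trials —
cluster-scale, provided for completeness).
"""
from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any

import numpy as np

from .mc import measure_diffusivity
from .pores import extrapolate_phi_c, fit_percolation_curve, percolation_curve
from .rates import fit_alpha, rate_distribution, rate_table, tail_mass_outside
from .scaling import CriticalConstants, fit_mu, mu_rg

_STAGES = ("percolate", "diffuse", "rates")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full experiment.

    Every stochastic stage derives its seeds from ``seed``; all lengths
    are in units of sigma and all times in MC sweeps.
    """

    out_dir: Path
    stages: tuple[str, ...] = _STAGES
    scale: str = "desk"
    seed: int = 0

    # percolation stage
    L_list: tuple[float, ...] = (50.0, 100.0, 150.0)
    n_configs_percolation: int = 200
    phi_grid_halfwidth_factor: float = 3.0

    # diffusion stage; t_max_list ramps with phi (slower relaxation near phi_c)
    delta_list: tuple[float, ...] = (0.1, 0.3, 2.0)
    phi_list: tuple[float, ...] = (0.10, 0.12, 0.14, 0.16)
    t_max_list: tuple[float, ...] = (1e6, 1e6, 1e6, 1.5e6)
    L_diffusion: float = 50.0
    n_configs_diffusion: int = 6
    n_tracers: int = 10

    # rates stage
    delta_rates: tuple[float, ...] = (0.01, 0.5, 2.0)
    phi_rates: float = 0.21
    L_rates: float = 70.0
    n_trials: int = 500
    max_pores: int | None = None
    step_cap: int = 10**5

    phi_c_fixed: float | None = None  # use this phi_c instead of the percolation stage

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for s in self.stages:
            if s not in _STAGES:
                raise ValueError(f"unknown stage {s!r}; valid: {_STAGES}")
        if len(self.t_max_list) != len(self.phi_list):
            raise ValueError("t_max_list must parallel phi_list")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def desk_config(out_dir, seed: int = 0, **overrides) -> RunConfig:
    """Scaled-down single-CPU preset (the default study conditions here)."""
    return RunConfig(out_dir=out_dir, scale="desk", seed=seed, **overrides)


def paper_config(out_dir, seed: int = 0, **overrides) -> RunConfig:
    """Full-scale study conditions (cluster-scale; not run in the tests)."""
    defaults = dict(
        L_list=(200.0, 500.0, 1000.0, 2000.0),
        n_configs_percolation=1000,
        delta_list=(0.01, 0.05, 0.1, 0.3, 0.5, 1.0, 1.5, 2.0),
        phi_list=(0.10, 0.13, 0.16, 0.18, 0.19, 0.20, 0.205, 0.2075),
        t_max_list=(1e7, 1e7, 1e7, 3e7, 3e7, 1e8, 1e8, 1e8),
        L_diffusion=200.0,
        n_configs_diffusion=300,
        delta_rates=(0.01, 0.3, 0.5, 1.0, 2.0),
        L_rates=300.0,
        n_trials=8000,
        step_cap=10**8,
    )
    defaults.update(overrides)
    return RunConfig(out_dir=out_dir, scale="paper", seed=seed, **defaults)


def _phi_grid_for(L: float, n_points: int = 9) -> np.ndarray:
    """Phi grid bracketing the finite-size wrapping transition at size L.

    Centred on the finite-size threshold (which sits slightly above the
    infinite-size phi_c for the wrapping criterion and drifts down as
    ~L^(-1/nu)) with a half-width several times the transition width, so
    that P spans well past [0.2, 0.8] as the tanh fit requires.
    """
    center = 0.2125 + 0.08 * L ** (-0.75)
    halfwidth = 0.25 * L ** (-0.75) + 0.004
    return np.linspace(center - halfwidth, center + halfwidth, n_points)


def run_percolation_stage(config: RunConfig, force: bool = False) -> dict[str, Any]:
    out = config.out_dir / "percolation.json"
    if out.exists() and not force:
        return json.loads(out.read_text())
    fits = {}
    curves = []
    for i, L in enumerate(config.L_list):
        grid = _phi_grid_for(L)
        curve = percolation_curve(
            grid, L, config.n_configs_percolation, seed=config.seed + 1000 * (i + 1)
        )
        fit = fit_percolation_curve(curve)
        fits[L] = fit
        curves.append(
            {
                "L": L,
                "phi": curve.phi_values.tolist(),
                "P": curve.P.tolist(),
                "stderr": curve.stderr.tolist(),
                "phi_c_L": fit.value,
                "delta_phi": fit.metadata["delta_phi"],
            }
        )
    final = extrapolate_phi_c(fits)
    result = {"phi_c": final.to_dict(), "curves": curves}
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result, indent=2))
    return result


def run_diffusion_stage(
    config: RunConfig, phi_c: float, force: bool = False
) -> dict[str, Any]:
    out = config.out_dir / "diffusion.json"
    if out.exists() and not force:
        return json.loads(out.read_text())
    per_delta: dict[str, Any] = {}
    for j, delta in enumerate(config.delta_list):
        # common random numbers across delta (paired mu comparison)
        D = {}
        for i, phi in enumerate(config.phi_list):
            fit = measure_diffusivity(
                phi=phi,
                L=config.L_diffusion,
                delta=delta,
                t_max=config.t_max_list[i],
                n_configs=config.n_configs_diffusion,
                n_tracers=config.n_tracers,
                seed=config.seed + 100 * i,
            )
            D[phi] = (fit.value, fit.stderr)
        mu_fit = fit_mu(D, phi_c=phi_c)
        per_delta[str(delta)] = {
            "D": {str(p): [v[0], v[1]] for p, v in D.items()},
            "mu": mu_fit.to_dict(),
        }
    result = {"phi_c_used": phi_c, "per_delta": per_delta}
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result, indent=2))
    return result


def run_rates_stage(config: RunConfig, force: bool = False) -> dict[str, Any]:
    from .matrix import generate_matrix
    from .pores import tessellate

    out = config.out_dir / "rates.json"
    if out.exists() and not force:
        return json.loads(out.read_text())
    matrix = generate_matrix(config.phi_rates, config.L_rates, seed=config.seed + 77)
    network = tessellate(matrix)
    pores = None
    if config.max_pores is not None:
        pores = np.arange(min(config.max_pores, network.n_triangles))
    per_delta: dict[str, Any] = {}
    for j, delta in enumerate(config.delta_rates):
        table = rate_table(
            matrix, network, delta=delta, n_trials=config.n_trials,
            seed=config.seed + 555 * (j + 1), pores=pores,
            step_cap=config.step_cap,
        )
        hist = rate_distribution(table.W_num[table.W_num > 0].to_numpy())
        alpha_fit = fit_alpha(hist)
        alpha = max(min(alpha_fit.value, 0.999), 0.0)
        per_delta[str(delta)] = {
            "alpha": alpha_fit.to_dict(),
            "mu_rg": mu_rg(alpha),
            "tail_mass_outside": tail_mass_outside(
                table.P_num.to_numpy(), table.P_TST.to_numpy()
            ),
            "n_pores": int(table.pore_id.nunique()),
        }
        table.to_csv(config.out_dir / f"rate_table_delta_{delta}.csv", index=False)
    result = {"per_delta": per_delta, "phi": config.phi_rates, "L": config.L_rates}
    config.out_dir.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(result, indent=2))
    return result


def run_experiment(config: RunConfig, force: bool = False) -> dict[str, Any]:
    """Run the configured stages in dependency order and write a report.

    Stage outputs are cached in ``config.out_dir``; re-running with the
    same config is a no-op on cached artifacts (``force=True`` recomputes).
    The report collects phi_c and the per-Delta exponents with all fit
    metadata.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": config.to_dict()}
    timings: dict[str, float] = {}
    phi_c = config.phi_c_fixed
    if "percolate" in config.stages:
        t0 = time.perf_counter()
        perc = run_percolation_stage(config, force=force)
        timings["percolate"] = round(time.perf_counter() - t0, 2)
        report["phi_c"] = perc["phi_c"]
        if phi_c is None:
            phi_c = perc["phi_c"]["value"]
    if "diffuse" in config.stages:
        if phi_c is None:
            raise RuntimeError(
                "diffuse stage needs phi_c: run the percolate stage first or "
                "set phi_c_fixed in the config"
            )
        t0 = time.perf_counter()
        diff = run_diffusion_stage(config, phi_c=phi_c, force=force)
        timings["diffuse"] = round(time.perf_counter() - t0, 2)
        report["diffusion"] = diff
    if "rates" in config.stages:
        t0 = time.perf_counter()
        rates = run_rates_stage(config, force=force)
        timings["rates"] = round(time.perf_counter() - t0, 2)
        report["rates"] = rates
    # wall times live in a sidecar so the report itself is deterministic
    (config.out_dir / "timings.json").write_text(json.dumps(timings, indent=2))
    (config.out_dir / "report.json").write_text(json.dumps(report, indent=2))
    return report


def validate_report(report: dict[str, Any]) -> list[str]:
    """Cross-stage consistency checks; returns the list of violations."""
    if not isinstance(report, dict) or "config" not in report:
        raise ValueError("malformed report: missing config block")
    violations: list[str] = []
    constants = CriticalConstants()
    if "phi_c" in report:
        phi_c = report["phi_c"]["value"]
        if not 0.15 < phi_c < 0.25:
            violations.append(f"phi_c = {phi_c:.4f} outside the plausible band")
    if "diffusion" in report:
        for delta, block in report["diffusion"]["per_delta"].items():
            D = {float(p): v[0] for p, v in block["D"].items()}
            phis = sorted(D)
            dvals = [D[p] for p in phis]
            if any(b > a * 1.02 for a, b in zip(dvals, dvals[1:])):
                violations.append(f"D(phi) not non-increasing at delta={delta}")
            if block["mu"]["value"] <= 0:
                violations.append(f"mu <= 0 at delta={delta}")
    if "rates" in report:
        for delta, block in report["rates"]["per_delta"].items():
            alpha = block["alpha"]["value"]
            if alpha >= 1:
                violations.append(
                    f"alpha = {alpha:.3f} >= 1 at delta={delta}: outside the "
                    "RG domain"
                )
                continue
            expected = mu_rg(max(alpha, 0.0), constants)
            if abs(block["mu_rg"] - expected) > 1e-9:
                violations.append(f"mu_rg inconsistent with alpha at delta={delta}")
    return violations
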