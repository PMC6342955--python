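#!/usr/bin/env python
"""Combine the stages: mu from dynamics vs the RG prediction from alpha.

Reads the cached stage outputs (or runs the full desk pipeline if absent),
tabulates mu(Delta) next to mu_RG = max(1.31, 1/(1 - alpha(Delta))), and
validates the cross-stage invariants of the report.

Run:  python analysis/05_exponent_synthesis.py [--seed 42] [--out-dir results]
"""
import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import crowdperc as cp
from crowdperc.pipeline import desk_config


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    config = desk_config(args.out_dir, seed=args.seed)
    report = cp.run_experiment(config)  # cached stages are reused

    print(f"phi_c = {report['phi_c']['value']:.5f}\n")
    print(f"{'Delta':>6} {'mu (dynamics)':>14} {'alpha':>7} {'mu_RG':>7}")
    mus = report["diffusion"]["per_delta"]
    rates = report["rates"]["per_delta"]
    for delta in sorted(set(mus) | set(rates), key=float):
        mu = mus.get(delta, {}).get("mu", {}).get("value")
        alpha = rates.get(delta, {}).get("alpha", {}).get("value")
        mu_rg = rates.get(delta, {}).get("mu_rg")
        print(
            f"{delta:>6} {'-':>14} {'-':>7} {'-':>7}"
            if mu is None and alpha is None
            else f"{delta:>6} "
            + (f"{mu:14.3f}" if mu is not None else f"{'-':>14}")
            + (f" {alpha:7.3f}" if alpha is not None else f" {'-':>7}")
            + (f" {mu_rg:7.3f}" if mu_rg is not None else f" {'-':>7}")
        )
    violations = cp.validate_report(report)
    if violations:
        print("\nreport validation FAILED:")
        for v in violations:
            print(" -", v)
        return 1
    print("\nreport validation passed: no cross-stage invariant violated.")
    return 0


if __name__ == "__main__":
    sys.exit(main())
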