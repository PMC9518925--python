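#!/usr/bin/env python
"""Scenario variations: what helps and what breaks network inference?

Runs the published variations of the base case (host-variability sources,
measurement/process noise levels, strength distributions, network
structures, matching rules, sample size) and ranks each against the base
case with the two-sided Mann-Whitney U test on per-replicate F1.

Writes results/variations/summary.tsv and per-scenario result directories.
The heavier scenarios (30 species, process noise, 3000 hosts) are included
only with --full; by default the sample-size scenario runs at 1000 hosts.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from glvnet.config import write_results
from glvnet.scenarios import builtin_scenarios, compare_f1, run_scenario

DESK = [
    "var_rK", "var_r_only", "var_K_only", "no_variation",
    "noise_low", "noise_high",
    "strengths_uniform", "strengths_unimodal",
    "producer_consumer", "hub",
]
FULL = ["species30", "process_noise_low", "process_noise_high",
        "hosts3000", "hosts3000_producer_consumer", "hosts3000_hub"]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=201)
    ap.add_argument("--networks", type=int, default=100)
    ap.add_argument("--full", action="store_true", help="include the heavy scenarios")
    ap.add_argument("--out", type=Path, default=Path("results/variations"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    reg = builtin_scenarios()
    names = DESK + (FULL if args.full else [])
    base = run_scenario(
        replace(reg["base"], master_seed=args.seed), n_networks=args.networks
    )
    write_results(base, args.out / "base")

    rows = [{
        "scenario": "base", "median_f1": float(np.median(base.f1())),
        "u": np.nan, "p": np.nan, "direction": "-",
    }]
    if not args.full:
        reg = dict(reg)
        reg["hosts1000"] = replace(reg["hosts3000"], name="hosts1000", n_hosts=1000)
        names = names + ["hosts1000"]
    for i, name in enumerate(names):
        cfg = replace(reg[name], master_seed=args.seed + i + 1)
        res = run_scenario(cfg, n_networks=args.networks)
        write_results(res, args.out / name)
        # rule variants score the same simulations under their own rule
        cmp = compare_f1(res.f1(), base.f1())
        med = float(np.median(res.f1()))
        rows.append({
            "scenario": name, "median_f1": med, "u": cmp.u, "p": cmp.p,
            "direction": ("higher" if med > np.median(base.f1()) else "lower")
            if cmp.p < 0.05 else "indistinguishable",
        })
        print(f"{name:28s} median F1 {med:.3f}  p={cmp.p:.2e} ({rows[-1]['direction']})")

    # matching-rule comparisons reuse the base simulations
    for rule in ("strongest_sign", "strict_both"):
        cmp = compare_f1(base.f1(rule=rule), base.f1())
        med = float(np.median(base.f1(rule=rule)))
        rows.append({
            "scenario": f"base[{rule}]", "median_f1": med, "u": cmp.u, "p": cmp.p,
            "direction": ("higher" if med > np.median(base.f1()) else "lower")
            if cmp.p < 0.05 else "indistinguishable",
        })
        print(f"base[{rule}]".ljust(28) + f" median F1 {med:.3f}  p={cmp.p:.2e}")

    pd.DataFrame(rows).to_csv(args.out / "summary.tsv", sep="\t", index=False)
    print(f"\nwritten to {args.out}")


if __name__ == "__main__":
    main()
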