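#!/usr/bin/env python
"""Opt-in genome-scale benchmark driver.

Reproduces the published-scale experiments on a user-supplied GEM
(e.g. iJO1366 or iMM904 in BiGG JSON, downloaded separately) with a core
definition YAML.  Expect minutes to hours per target on a full GEM; this
is deliberately not part of the test suite.

Examples:
    python scripts/benchmark_paper.py --model iJO1366.json \
        --core varma_core.yaml --target his__L_c --demand-from-biomass \
        --max-alternatives 20
    python scripts/benchmark_paper.py --model iJO1366.json \
        --core varma_core.yaml --target succ_c --demand 1e-3 --no-core
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import time

from lumpnet import (build_mini_model, build_problem, cmol_yield,
                     dedupe_lumps, define_core, demand_for_target,
                     enumerate_alternatives, load_model, lump_subnetwork,
                     mu_max, parse_biomass, rank_lumps, split_and_gate)

try:
    import yaml
except ImportError:  # pragma: no cover
    yaml = None


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", required=True)
    parser.add_argument("--core", help="core definition YAML "
                        "(core_reactions, core_metabolites_extra, "
                        "always_on, carbon_cap)")
    parser.add_argument("--no-core", action="store_true",
                        help="no core beyond the medium (industrial-"
                        "chemical mode: only exchanges stay ungated)")
    parser.add_argument("--target", action="append", required=True)
    parser.add_argument("--demand", type=float, default=None)
    parser.add_argument("--demand-from-biomass", action="store_true",
                        help="demand = n_j * mu_max from the biomass")
    parser.add_argument("--mode", default="minimal-only",
                        choices=["minimal-only", "up-to-size"])
    parser.add_argument("--size-cap", type=int, default=None)
    parser.add_argument("--max-alternatives", type=int, default=50)
    parser.add_argument("--timeout", type=float, default=3600,
                        help="MILP time limit per solve (s)")
    parser.add_argument("--yield-source", default=None,
                        help="carbon source metabolite for C-mol yields")
    parser.add_argument("--out", default="-")
    args = parser.parse_args()
    logging.basicConfig(level=logging.INFO)

    model = load_model(args.model)
    if args.no_core:
        partition = define_core(model, [], gate_transports=False)
        carbon_cap = None
    else:
        with open(args.core) as fh:
            cfg = yaml.safe_load(fh)
        partition = define_core(model, cfg.get("core_reactions", []),
                                cfg.get("core_metabolites_extra", []),
                                gate_transports=not cfg.get("always_on"))
        if cfg.get("always_on"):
            extra = set(cfg["always_on"])
            partition.always_on |= extra
            partition.noncore_reactions -= extra
            partition.validate(model)
        carbon_cap = cfg.get("carbon_cap")

    composition = None
    mu = None
    if args.demand_from_biomass:
        composition = parse_biomass(model)
        mu = mu_max(model)
        print(f"# mu_max = {mu:.4f}/h", file=sys.stderr)

    gated = split_and_gate(model, partition, carbon_cap)
    report = {}
    for target in args.target:
        n_j = None
        if composition is not None:
            try:
                n_j = composition.demand(target)
            except Exception:
                n_j = None
        demand = args.demand or demand_for_target(n_j, mu)
        t0 = time.time()
        problem = build_problem(gated, target, demand)
        result = enumerate_alternatives(problem, mode=args.mode,
                                        size_cap=args.size_cap,
                                        max_count=args.max_alternatives,
                                        timeout=args.timeout)
        lumps = dedupe_lumps([
            lump_subnetwork(model, partition, sub, demand)
            for sub in result if sub.reactions])
        entry = {
            "s_min": result.s_min,
            "n_alternatives": len(result),
            "truncated": result.truncated,
            "n_unique_lumps": len(lumps),
            "lumps": [l.equation() for l in lumps],
            "seconds": round(time.time() - t0, 1),
        }
        if args.yield_source and lumps:
            records = []
            for lump in lumps:
                mini = build_mini_model(model, partition, lump, target)
                records.append(
                    cmol_yield(mini, target, args.yield_source, lump=lump))
            entry["yields"] = [round(r.yield_cmol, 2)
                               for r in rank_lumps(records)]
        report[target] = entry
        print(f"# {target}: S_min={entry['s_min']} "
              f"alts={entry['n_alternatives']} "
              f"unique_lumps={entry['n_unique_lumps']} "
              f"({entry['seconds']}s)", file=sys.stderr)

    text = json.dumps(report, indent=2)
    if args.out == "-":
        print(text)
    else:
        with open(args.out, "w") as fh:
            fh.write(text)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
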