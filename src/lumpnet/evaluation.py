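"""Desk-scale evaluation studies on seeded toy fixtures.

These functions drive the whole pipeline — MILP enumeration against the
brute-force oracle, lumping with elemental audits and flux-equivalence
checks, balancer recovery, model reduction and yield ranking — on toy
GEMs small enough (|R^ncGEM| <= 14) for exhaustive certification.  They
power ``scripts/acceptance.py`` and the acceptance test suite.
"""

from __future__ import annotations

from fractions import Fraction

from .fba import fba, mu_max
from .gem_io import sink_id_for
from .lumping import LumpedReaction, dedupe_lumps, lump_subnetwork
from .model import MetabolicModel, to_cobra
from .partition import split_and_gate
from .reduction import assemble_candidate_model, select_minimal_lump_set
from .subnetworks import build_problem, enumerate_alternatives
from .toys import (ToySpec, brute_force_min_subnetworks, make_toy_gem,
                   make_yield_demo)
from .yields import build_mini_model, cmol_yield, rank_lumps

#: Fixture archetypes cycled over seeds; all keep |R^ncGEM| <= 14.
_TEMPLATES = (
    dict(n_core_reactions=4, planted_paths=((2, 2),), branch_balancers=0,
         n_decoys=2),
    dict(n_core_reactions=3, planted_paths=((3, 2),), branch_balancers=1,
         n_decoys=2),
    dict(n_core_reactions=4, planted_paths=((2, 1), (3, 1)),
         branch_balancers=0, n_decoys=3),
    dict(n_core_reactions=3, planted_paths=((4, 1),), branch_balancers=2,
         n_decoys=3),
    dict(n_core_reactions=5, planted_paths=((2, 3),), branch_balancers=0,
         n_decoys=4),
    dict(n_core_reactions=4, planted_paths=((3, 1),), branch_balancers=0,
         n_decoys=2, core_target=True),
)


def fixture_specs(seed: int, n: int):
    """n deterministic ToySpecs derived from one base seed."""
    for i in range(n):
        template = _TEMPLATES[i % len(_TEMPLATES)]
        yield ToySpec(seed=seed + i, **template)


def _minimal_sets(model, partition, target, demand):
    gated = split_and_gate(model, partition)
    problem = build_problem(gated, target, demand)
    result = enumerate_alternatives(problem, mode="minimal-only")
    return result


def oracle_agreement_study(seed: int, n_fixtures: int = 50) -> dict:
    """MILP S_min and minimal-set collection vs the brute-force oracle."""
    agree = 0
    smin_agree = 0
    for spec in fixture_specs(seed, n_fixtures):
        fx = make_toy_gem(spec, certify=False)
        target = fx.targets[0]
        oracle = brute_force_min_subnetworks(
            fx.model, fx.partition, target, spec.demand)
        result = _minimal_sets(fx.model, fx.partition, target, spec.demand)
        milp_sets = {s.reactions for s in result}
        oracle_smin = min(len(s) for s in oracle)
        if result.s_min == oracle_smin:
            smin_agree += 1
        if milp_sets == oracle:
            agree += 1
    return {"n": n_fixtures, "set_agreement_rate": agree / n_fixtures,
            "smin_agreement_rate": smin_agree / n_fixtures}


def _max_target_flux(model: MetabolicModel, rxn_ids, target: str) -> float:
    """LP maximum of a fresh sink on the given reaction subset."""
    sub = model.subnetwork_model(rxn_ids)
    cbm = to_cobra(sub)
    sid = sink_id_for(target)
    if sid not in cbm.reactions:
        import cobra
        sink = cobra.Reaction(sid)
        cbm.add_reactions([sink])
        sink.add_metabolites({cbm.metabolites.get_by_id(target): -1.0})
        sink.bounds = (0.0, 1000.0)
    cbm.objective = sid
    v = cbm.slim_optimize(error_value=float("nan"))
    return v if cbm.solver.status == "optimal" else 0.0


def lump_soundness_study(seed: int, n_fixtures: int = 20) -> dict:
    """Elemental residuals and subnetwork<->lump flux equivalence."""
    max_residual = 0.0
    max_rel_err = 0.0
    n_lumps = 0
    for spec in fixture_specs(seed, n_fixtures):
        if spec.core_target:
            continue
        fx = make_toy_gem(spec, certify=False)
        target = fx.targets[0]
        result = _minimal_sets(fx.model, fx.partition, target, spec.demand)
        for sub in result:
            lump = lump_subnetwork(fx.model, fx.partition, sub, spec.demand)
            n_lumps += 1
            for el, res in lump.balance_report.items():
                if el == "unaudited":
                    continue
                max_residual = max(max_residual, abs(float(res)))
            # maximal target synthesis: core+subnetwork vs core+lump
            with_sub = _max_target_flux(
                fx.model,
                sorted(fx.partition.ungated_reactions | set(sub.reactions)),
                target)
            mini = build_mini_model(fx.model, fx.partition, lump, target)
            with_lump = _max_target_flux(
                mini, [r.id for r in mini.reactions], target)
            denom = max(abs(with_sub), 1e-12)
            max_rel_err = max(max_rel_err, abs(with_sub - with_lump) / denom)
    return {"n_lumps": n_lumps, "max_elemental_residual": max_residual,
            "max_flux_equivalence_rel_err": max_rel_err}


def balancer_recovery_study(seed: int, n_fixtures: int = 20) -> dict:
    """Fraction of balancer fixtures whose minimal sets all include every
    planted balancing reaction."""
    recovered = 0
    for i in range(n_fixtures):
        spec = ToySpec(seed=seed + 1000 + i, n_core_reactions=3,
                       planted_paths=((3, 1),),
                       branch_balancers=1 + (i % 2), n_decoys=2)
        fx = make_toy_gem(spec, certify=False)
        target = fx.targets[0]
        result = _minimal_sets(fx.model, fx.partition, target, spec.demand)
        balancers = {rid for s in fx.ground_truth[target]["min_sets"]
                     for rid in s if rid.startswith("BAL")}
        assert balancers, "balancer fixture without balancers"
        if result.subnetworks and all(
                balancers <= set(s.reactions) for s in result):
            recovered += 1
    return {"n": n_fixtures, "recovery_rate": recovered / n_fixtures}


def reduction_study(seed: int) -> dict:
    """Reduced-model growth vs the parent toy GEM, and lump necessity."""
    spec = ToySpec(seed=seed + 2000, n_core_reactions=4,
                   planted_paths=((2, 2),), branch_balancers=0, n_targets=2,
                   n_decoys=2, with_biomass=True)
    fx = make_toy_gem(spec, certify=False)
    model, partition = fx.model, fx.partition
    mu_gem = mu_max(model)
    gated = split_and_gate(model, partition)
    lumps: list[LumpedReaction] = []
    for target in fx.targets:
        problem = build_problem(gated, target, spec.demand)
        for sub in enumerate_alternatives(problem):
            lumps.append(lump_subnetwork(model, partition, sub, spec.demand))
    lumps = dedupe_lumps(lumps)
    candidate = assemble_candidate_model(model, partition, lumps, "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    mu_red = reduced.mu_at_medium
    gap = (mu_gem - mu_red) / mu_gem if mu_gem else float("inf")
    # removing any selected lump must drop growth below the fixed yield
    lump_ids = [r.id for r in reduced.model.reactions
                if r.id.startswith("LMP_")]
    all_necessary = True
    for rid in lump_ids:
        rest = [r.id for r in reduced.model.reactions if r.id != rid]
        pruned = reduced.model.subnetwork_model(rest)
        pruned.objective_reaction_id = "BIOMASS"
        res = fba(pruned, "BIOMASS")
        mu_ko = res.objective_value if res.ok else 0.0
        if mu_ko >= mu_red * (1 - 1e-4):
            all_necessary = False
    return {"mu_gem": mu_gem, "mu_reduced": mu_red, "rel_gap": gap,
            "n_candidate_lumps": len(lumps),
            "n_selected_lumps": len(lump_ids),
            "all_selected_lumps_necessary": all_necessary}


def yield_study() -> dict:
    """Hand-derivable C-mol yields: a conserving lump (1.0) and a lump
    losing one CO2 per six-carbon target (6/7)."""
    model, partition, stoichs = make_yield_demo()
    records = []
    for k, stoich in enumerate(stoichs):
        lump = LumpedReaction("tgt", dict(stoich), provenance=[k])
        mini = build_mini_model(model, partition, lump, "tgt")
        records.append(cmol_yield(mini, "tgt", "glc", lump=lump))
    ranked = rank_lumps(records)
    yields = [r.yield_cmol for r in ranked]
    return {"yields_ranked": yields,
            "yield_conserving": max(yields),
            "yield_co2_loss": min(yields),
            "expected_co2_loss": float(Fraction(6, 7)),
            "all_in_unit_interval": all(0 <= y <= 1 for y in yields),
            "ranking_correct": yields == sorted(yields, reverse=True)}
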