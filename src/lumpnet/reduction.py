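"""Assemble a reduced core model from lumps and select a minimal lump set.

The candidate model is the core network plus every deduplicated lump,
the parent model's transport/exchange reactions that touch only included
species, the biomass reaction and configured sinks.  A MILP then fixes
the candidate's maximal biomass yield and minimizes the number of active
lumped reactions; the reduced model keeps only the selected lumps and
re-attains the fixed growth rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import AssemblyError
from .fba import fba
from .lumping import LumpedReaction
from .model import MetabolicModel, Reaction, to_cobra
from .partition import CorePartition

log = logging.getLogger(__name__)

#: Relative slack when fixing the maximal biomass yield in the MILP.
YIELD_FIX_SLACK = 1e-6

#: Relative tolerance the re-assembled reduced model must re-attain.
REATTAIN_TOL = 1e-4

LUMP_BIG_M = 1000.0


@dataclass
class ReducedModel:
    model: MetabolicModel
    selected_lumps: list[LumpedReaction]
    provenance: dict[str, list[int]] = field(default_factory=dict)
    mu_at_medium: float = 0.0


def _base_names(model: MetabolicModel, met_ids) -> set[str]:
    out = set()
    for mid in met_ids:
        met = model.metabolite(mid)
        suffix = f"_{met.compartment}"
        out.add(mid[: -len(suffix)] if met.compartment and mid.endswith(suffix)
                else mid)
    return out


def _is_transport(model: MetabolicModel, rxn: Reaction) -> bool:
    """Same base species moved between compartments."""
    compartments = {model.metabolite(m).compartment for m in rxn.stoichiometry}
    if len(compartments) < 2:
        return False
    reactants = [m for m, c in rxn.stoichiometry.items() if c < 0]
    products = [m for m, c in rxn.stoichiometry.items() if c > 0]
    return bool(_base_names(model, reactants) & _base_names(model, products))


def lump_reaction_id(target_id: str, index: int) -> str:
    return f"LMP_{target_id}_{index}"


def assemble_candidate_model(model: MetabolicModel, partition: CorePartition,
                             lumps, biomass_id: str,
                             include_sinks: bool = True) -> MetabolicModel:
    """Core + all lumps + compatible transports/exchanges + biomass (+ sinks).

    Every biomass participant must be suppliable by a core reaction, a
    lump or a boundary reaction; an orphan species raises
    :class:`AssemblyError` naming it.
    """
    biomass = model.reaction(biomass_id)
    rxn_ids = sorted((partition.core_reactions | partition.always_on)
                     - {biomass_id})
    species = model.species_of(rxn_ids) | set(biomass.stoichiometry)
    lump_rxns = []
    counters: dict[str, int] = {}
    for lump in lumps:
        k = counters.get(lump.target_id, 0)
        counters[lump.target_id] = k + 1
        lump_rxns.append((lump_reaction_id(lump.target_id, k), lump))
        species |= set(lump.stoichiometry)
    for rxn in model.reactions:
        if rxn.id in set(rxn_ids) or rxn.id == biomass_id:
            continue
        is_compatible = set(rxn.stoichiometry) <= species
        if not is_compatible:
            continue
        if rxn.is_boundary:
            if include_sinks or rxn.id in model.medium:
                rxn_ids.append(rxn.id)
        elif _is_transport(model, rxn):
            rxn_ids.append(rxn.id)

    producible = set()
    for rid in rxn_ids:
        rxn = model.reaction(rid)
        for met, coeff in rxn.stoichiometry.items():
            if coeff > 0 or rxn.lower_bound < 0 or rxn.is_boundary:
                producible.add(met)
    for _, lump in lump_rxns:
        producible.update(m for m, c in lump.stoichiometry.items() if c > 0)
    orphans = [m for m, c in biomass.stoichiometry.items()
               if c < 0 and m not in producible]
    if orphans:
        raise AssemblyError(
            "biomass species with no supplying reaction or lump: "
            f"{sorted(orphans)}")

    mets = [m for m in model.metabolites if m.id in species]
    rxns = [model.reaction(rid).copy() for rid in rxn_ids]
    rxns.append(biomass.copy())
    for rid, lump in lump_rxns:
        rxns.append(Reaction(rid, dict(lump.stoichiometry), 0.0, 1000.0,
                             subsystem="lumped"))
    medium = {rid: up for rid, up in model.medium.items() if rid in set(rxn_ids)}
    out = MetabolicModel(mets, rxns, biomass_id, medium, f"{model.id}_reduced")
    out.lump_index = {rid: lump for rid, lump in lump_rxns}
    return out


def select_minimal_lump_set(candidate: MetabolicModel,
                            lumps=None) -> ReducedModel:
    """Fix the maximal biomass yield, then minimize active lumps (MILP)."""
    lump_ids = sorted(getattr(candidate, "lump_index", {}) or
                      {r.id for r in candidate.reactions
                       if r.id.startswith("LMP_")})
    biomass_id = candidate.objective_reaction_id
    cbm = to_cobra(candidate)
    cbm.objective = biomass_id
    mu_star = cbm.slim_optimize(error_value=float("nan"))
    if not (mu_star > 0):
        raise AssemblyError(
            f"candidate model does not grow (mu={mu_star!r})")
    cbm.reactions.get_by_id(biomass_id).lower_bound = \
        mu_star * (1 - YIELD_FIX_SLACK)

    active, new = {}, []
    for rid in lump_ids:
        rxn = cbm.reactions.get_by_id(rid)
        a = cbm.problem.Variable(f"use__{rid}", type="binary")
        cons = cbm.problem.Constraint(
            rxn.forward_variable + rxn.reverse_variable - LUMP_BIG_M * a,
            ub=0, name=f"usecons__{rid}")
        active[rid] = a
        new.extend([a, cons])
    cbm.add_cons_vars(new)
    cbm.objective = cbm.problem.Objective(sum(active.values()), direction="min")
    cbm.slim_optimize(error_value=float("nan"))
    if cbm.solver.status != "optimal":
        raise AssemblyError(
            "lump-selection MILP failed at the fixed yield; consider "
            f"relaxing the slack (status {cbm.solver.status!r})")
    selected_ids = [rid for rid in lump_ids if active[rid].primal > 0.5]

    keep = [r.id for r in candidate.reactions
            if r.id not in set(lump_ids) or r.id in set(selected_ids)]
    reduced = candidate.subnetwork_model(keep, id=f"{candidate.id}_selected")
    reduced.objective_reaction_id = biomass_id
    lump_index = getattr(candidate, "lump_index", {})
    selected_lumps = [lump_index[rid] for rid in selected_ids
                      if rid in lump_index]
    res = fba(reduced, biomass_id)
    mu_red = res.objective_value if res.ok else 0.0
    if mu_red < mu_star * (1 - REATTAIN_TOL):
        raise AssemblyError(
            f"reduced model re-attains mu={mu_red:.6g} < "
            f"{mu_star:.6g} * (1 - {REATTAIN_TOL})")
    provenance = {rid: list(lump_index[rid].provenance)
                  for rid in selected_ids if rid in lump_index}
    return ReducedModel(reduced, selected_lumps, provenance, mu_red)


def validate_growth(reduced: ReducedModel | MetabolicModel,
                    biomass_id: str | None = None) -> float:
    """FBA maximum of biomass flux at the model's medium (1/h)."""
    model = reduced.model if isinstance(reduced, ReducedModel) else reduced
    res = fba(model, biomass_id or model.objective_reaction_id)
    mu = res.objective_value if res.ok else 0.0
    if isinstance(reduced, ReducedModel):
        reduced.mu_at_medium = mu
    return mu


def write_selection_report(candidate: MetabolicModel, reduced: ReducedModel,
                           path) -> None:
    """TSV report: lump id, selected yes/no, flux at the reduced optimum."""
    res = fba(reduced.model, reduced.model.objective_reaction_id,
              return_fluxes=True)
    selected = {r.id for r in reduced.model.reactions if r.id.startswith("LMP_")}
    with open(path, "w") as fh:
        fh.write("lump\tselected\tflux_at_optimum\n")
        for rid in sorted(getattr(candidate, "lump_index", {})):
            sel = "yes" if rid in selected else "no"
            flux = res.fluxes.get(rid, 0.0)
            fh.write(f"{rid}\t{sel}\t{flux:.6g}\n")
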