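"""Core/non-core partitioning and big-M flux gating.

The user selects a core subsystem (e.g. glycolysis + PPP + TCA + ETC);
every other reaction is a candidate subnetwork member and receives a
binary gate ``z``.  Gating uses the split forward/backward flux variables
F, B >= 0 (v = F - B) that cobrapy maintains for every reaction, with the
constraint

    F_i + B_i + C * z_i <= C

so that ``z_i = 1`` forces zero flux regardless of directionality, and
``z_i = 0`` relaxes to ``F_i + B_i <= C``.  C is the carbon-atom flux the
cell can take up from the medium (number of carbon atoms of the limiting
carbon source times its uptake bound), the smallest valid big-M.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import LookupError_, ParameterError
from .model import MetabolicModel, to_cobra

#: Big-M fallback when the medium has no single finite carbon source.
DEFAULT_BIG_M = 1000.0


@dataclass
class CorePartition:
    """The R^core/M^core vs non-core split of a model.

    ``always_on`` reactions (typically exchanges) are exempt from gating;
    they belong to neither the core nor the candidate set.
    """

    core_reactions: set[str]
    core_metabolites: set[str]
    noncore_reactions: set[str]
    noncore_metabolites: set[str]
    always_on: set[str] = field(default_factory=set)

    def validate(self, model: MetabolicModel) -> None:
        all_rxns = set(model.reaction_ids)
        parts = [self.core_reactions, self.noncore_reactions, self.always_on]
        if set().union(*parts) != all_rxns:
            raise ValueError("partition does not cover all reactions")
        if (self.core_reactions & self.noncore_reactions
                or self.core_reactions & self.always_on
                or self.noncore_reactions & self.always_on):
            raise ValueError("partition classes overlap")
        touched = model.species_of(self.core_reactions)
        if not touched <= self.core_metabolites:
            raise ValueError("core_metabolites misses species of core reactions")
        if self.noncore_metabolites != set(model.metabolite_ids) - self.core_metabolites:
            raise ValueError("noncore_metabolites is not the complement of "
                             "core_metabolites")

    @property
    def ungated_reactions(self) -> set[str]:
        return self.core_reactions | self.always_on


def define_core(model: MetabolicModel, core_reaction_ids,
                extra_core_metabolites=(), gate_transports: bool = True) -> CorePartition:
    """Build a :class:`CorePartition` from a core reaction list.

    ``extra_core_metabolites`` admits cofactor pairs and inorganic species
    into M^core even when no core reaction touches them.  With
    ``gate_transports=False``, boundary reactions (exchanges/sinks) outside
    the core are exempted from gating instead of being subnetwork
    candidates.
    """
    core_reaction_ids = list(core_reaction_ids)
    unknown = [r for r in core_reaction_ids if not model.has_reaction(r)]
    unknown += [m for m in extra_core_metabolites if not model.has_metabolite(m)]
    if unknown:
        raise LookupError_(f"unknown identifiers in core definition: {sorted(unknown)}")

    core_rxns = set(core_reaction_ids)
    core_mets = model.species_of(core_rxns) | set(extra_core_metabolites)
    always_on = set()
    if not gate_transports:
        always_on = {r.id for r in model.boundary_reactions} - core_rxns
    noncore_rxns = set(model.reaction_ids) - core_rxns - always_on
    noncore_mets = set(model.metabolite_ids) - core_mets
    part = CorePartition(core_rxns, core_mets, noncore_rxns, noncore_mets,
                         always_on)
    part.validate(model)
    return part


def default_carbon_cap(model: MetabolicModel) -> float:
    """C = (carbon atoms of the limiting carbon source) x (uptake bound).

    Falls back to a configured big-M when the medium has zero or several
    carbon sources, or an unbounded uptake.
    """
    carbon_sources = []
    for ex_id, uptake in model.medium.items():
        if not model.has_reaction(ex_id):
            continue
        rxn = model.reaction(ex_id)
        if not rxn.is_boundary:
            continue
        met = model.metabolite(next(iter(rxn.stoichiometry)))
        if met.n_carbon > 0 and uptake > 0:
            carbon_sources.append((met.n_carbon, float(uptake)))
    if len(carbon_sources) != 1 or not math.isfinite(carbon_sources[0][1]):
        return DEFAULT_BIG_M
    n_c, uptake = carbon_sources[0]
    return n_c * uptake


@dataclass
class SplitGatedModel:
    """A solver-ready model with binary gates on all non-core reactions.

    ``cobra_model`` owns the optlang problem; ``z`` maps each non-core
    reaction id to its binary variable and ``gates`` to the gating
    constraint.  ``source`` keeps the exact-rational model for rebuilding
    verification LPs.
    """

    cobra_model: object
    source: MetabolicModel
    partition: CorePartition
    carbon_cap: float
    z: dict[str, object]
    gates: dict[str, object]

    @property
    def n_binaries(self) -> int:
        return len(self.z)


def split_and_gate(model: MetabolicModel, partition: CorePartition,
                   carbon_cap: float | None = None) -> SplitGatedModel:
    """Split all reactions into F/B components and gate the non-core ones.

    Irreversible reactions keep a backward variable fixed at 0 by its
    bounds, so the L1 and gating machinery treats every reaction uniformly.
    """
    if carbon_cap is None:
        carbon_cap = default_carbon_cap(model)
    if not (carbon_cap > 0):
        raise ParameterError(f"carbon cap must be > 0, got {carbon_cap}")
    partition.validate(model)
    cbm = to_cobra(model)
    cbm.objective = cbm.problem.Objective(0)
    z_vars, gate_cons = {}, {}
    new = []
    for rid in sorted(partition.noncore_reactions):
        rxn = cbm.reactions.get_by_id(rid)
        z = cbm.problem.Variable(f"z__{rid}", type="binary")
        gate = cbm.problem.Constraint(
            rxn.forward_variable + rxn.reverse_variable + carbon_cap * z,
            ub=carbon_cap, name=f"gate__{rid}")
        z_vars[rid] = z
        gate_cons[rid] = gate
        new.extend([z, gate])
    cbm.add_cons_vars(new)
    return SplitGatedModel(cbm, model, partition, carbon_cap, z_vars, gate_cons)
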