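"""Carbon-mole yield ranking of alternative lumped reactions.

Each lump is evaluated on its own "mini" model — the core network, the
lump, the target sink and the medium exchanges — by maximizing target
synthesis at a fixed carbon-source uptake.  The C-mol yield

    (C atoms of target * v_sink) / (C atoms of source * v_uptake)

lies in [0, 1] for a sole carbon source (carbon conservation) and ranks
the alternatives; the core may re-assimilate lump by-products, so the
mini-model yield can exceed the naive stoichiometric carbon fraction of
the lump alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import AssemblyError, LookupError_
from .gem_io import sink_id_for
from .lumping import FluxDistribution, LumpedReaction
from .model import MetabolicModel, Reaction, to_cobra
from .partition import CorePartition


@dataclass
class YieldRecord:
    lump: LumpedReaction
    carbon_source: str
    yield_cmol: float
    optimum_fluxes: FluxDistribution


def build_mini_model(model: MetabolicModel, partition: CorePartition,
                     lumps, target_id: str) -> MetabolicModel:
    """Core + lump(s) + target sink + medium/boundary exchanges, nothing else."""
    if isinstance(lumps, LumpedReaction):
        lumps = [lumps]
    rxn_ids = sorted(partition.core_reactions | partition.always_on)
    species = model.species_of(rxn_ids) | {target_id}
    for lump in lumps:
        for met in lump.stoichiometry:
            if not model.has_metabolite(met):
                raise AssemblyError(
                    f"lump for {lump.target_id} references unknown species "
                    f"{met!r}")
        species |= set(lump.stoichiometry)
    # boundary reactions of the parent whose species live in the mini model
    for rxn in model.boundary_reactions:
        if set(rxn.stoichiometry) <= species:
            rxn_ids.append(rxn.id)
    rxn_ids = list(dict.fromkeys(rxn_ids))
    mets = [m for m in model.metabolites if m.id in species]
    rxns = [model.reaction(rid).copy() for rid in rxn_ids]
    for k, lump in enumerate(lumps):
        rxns.append(Reaction(f"LMP_{lump.target_id}_{k}",
                             dict(lump.stoichiometry), 0.0, 1000.0,
                             subsystem="lumped"))
    sid = sink_id_for(target_id)
    if sid not in {r.id for r in rxns}:
        rxns.append(Reaction(sid, {target_id: Fraction(-1)}, 0.0, 1000.0,
                             subsystem="lumpnet-sink"))
    medium = {rid: up for rid, up in model.medium.items()
              if rid in set(rxn_ids)}
    return MetabolicModel(mets, rxns, None, medium, f"{model.id}_mini_{target_id}")


def _uptake_exchange(mini: MetabolicModel, source: str) -> Reaction:
    for rxn in mini.boundary_reactions:
        if next(iter(rxn.stoichiometry)) == source and rxn.lower_bound < 0:
            return rxn
    raise LookupError_(f"no uptake exchange for carbon source {source!r}")


def cmol_yield(mini: MetabolicModel, target_id: str, source: str,
               lump: LumpedReaction | None = None,
               uptake: float | None = None) -> YieldRecord:
    """Maximize the target sink and report the C-mol yield on the source.

    ``uptake`` defaults to the exchange's uptake bound; the denominator is
    the bound (the medium's carbon supply), not the realized uptake.
    """
    src_met = mini.metabolite(source)
    tgt_met = mini.metabolite(target_id)
    if src_met.formula is None or src_met.n_carbon == 0:
        raise LookupError_(
            f"carbon source {source!r} lacks a carbon-containing formula")
    if tgt_met.formula is None:
        raise LookupError_(f"target {target_id!r} has no formula")
    exch = _uptake_exchange(mini, source)
    if uptake is None:
        uptake = -exch.lower_bound
    if not (0 < uptake < float("inf")):
        raise LookupError_(
            f"source exchange {exch.id} needs a finite uptake bound")
    cbm = to_cobra(mini)
    cbm.reactions.get_by_id(exch.id).lower_bound = -uptake
    sid = sink_id_for(target_id)
    cbm.objective = sid
    v_sink = cbm.slim_optimize(error_value=float("nan"))
    if cbm.solver.status != "optimal":
        v_sink = 0.0
    fluxes = {r.id: r.flux for r in cbm.reactions} if v_sink else {}
    y = (tgt_met.n_carbon * v_sink) / (src_met.n_carbon * uptake)
    return YieldRecord(lump, source, float(y),
                       FluxDistribution(fluxes, abs(v_sink), abs(v_sink) or 1.0))


def rank_lumps(records) -> list[YieldRecord]:
    """Sort descending by yield; ties by lump size then equation string."""
    targets = {r.lump.target_id for r in records if r.lump is not None}
    if len(targets) > 1:
        raise ValueError(f"records mix targets: {sorted(targets)}")
    sources = {r.carbon_source for r in records}
    if len(sources) > 1:
        raise ValueError(f"records mix carbon sources: {sorted(sources)}")
    return sorted(records, key=lambda r: (
        -r.yield_cmol,
        r.lump.size if r.lump is not None else 0,
        r.lump.equation() if r.lump is not None else ""))


def write_yield_report(records, path, target_id: str) -> None:
    """TSV report: target, lump equation, yield, rank."""
    ranked = rank_lumps(list(records))
    with open(path, "w") as fh:
        fh.write("target\tlump\tyield_cmol\trank\n")
        for k, rec in enumerate(ranked, start=1):
            eq = rec.lump.equation() if rec.lump is not None else ""
            fh.write(f"{target_id}\t{eq}\t{rec.yield_cmol:.2f}\t{k}\n")
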