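"""Collapse a subnetwork into one elementally balanced lumped reaction.

Given a minimal subnetwork S^j for target j, an L1 (net-flux) minimization
over the subnetwork reactions — core fluxes free, sink fixed at the
demand — yields a stoichiometrically proportional flux distribution
(alternative L1 optima are possible and flagged as degenerate).  Summing
the stoichiometric columns of the subnetwork weighted by these fluxes and
normalizing to +1 mol of target produces the lumped reaction: it contains
only core metabolites, the target, and drained by-products; every internal
intermediate cancels exactly, so elemental and charge balances carry over
from the member reactions.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from fractions import Fraction

from .errors import LumpingResidueError, ThermoInfeasibleError
from .gem_io import sink_id_for
from .model import MetabolicModel, to_cobra
from .partition import CorePartition
from .subnetworks import Subnetwork

log = logging.getLogger(__name__)

#: Coefficients below this (per mol target) are numerical noise and dropped.
COEFF_DROP_TOL = 1e-6

#: Denominator cap when snapping lump coefficients to small rationals.
LUMP_DENOMINATOR_CAP = 48

#: Flux magnitude below which a subnetwork member is flagged as slack.
SLACK_FLUX_TOL = 1e-9


@dataclass
class FluxDistribution:
    """Net fluxes on the core+subnetwork+sink model, L1-minimal on S^j."""

    values: dict[str, float]
    objective_value: float
    demand: float


@dataclass
class LumpedReaction:
    """Normalized net stoichiometry of a subnetwork (target coefficient +1)."""

    target_id: str
    stoichiometry: dict[str, Fraction | float]
    provenance: list[int] = field(default_factory=list)
    balance_report: dict[str, Fraction | float] = field(default_factory=dict)
    degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.stoichiometry)

    def equation(self) -> str:
        """Human-readable ``A + 2 B -> C`` form, alphabetical per side."""

        def side(items):
            parts = []
            for met, coeff in sorted(items):
                c = abs(coeff)
                parts.append(met if c == 1 else f"{_fmt(c)} {met}")
            return " + ".join(parts)

        reactants = [(m, c) for m, c in self.stoichiometry.items() if c < 0]
        products = [(m, c) for m, c in self.stoichiometry.items() if c > 0]
        return f"{side(reactants)} -> {side(products)}"


def _fmt(c) -> str:
    if isinstance(c, Fraction):
        return str(c.numerator) if c.denominator == 1 else f"{c}"
    return f"{c:.9g}"


def minimize_net_flux(model: MetabolicModel, partition: CorePartition,
                      subnetwork: Subnetwork, demand: float,
                      directionality_bounds: dict | None = None) -> FluxDistribution:
    """Minimize sum of |v_i| over subnetwork reactions at fixed demand.

    ``directionality_bounds`` (reaction id -> (lb, ub)) optionally tightens
    reactions, e.g. from thermodynamic pre-processing; infeasibility under
    such tightening raises :class:`ThermoInfeasibleError`.
    """
    rxn_ids = sorted(partition.ungated_reactions | set(subnetwork.reactions))
    cbm = to_cobra(model, rxn_ids)
    sid = sink_id_for(subnetwork.target_id)
    if sid not in cbm.reactions:
        import cobra
        sink = cobra.Reaction(sid)
        cbm.add_reactions([sink])
        sink.add_metabolites(
            {cbm.metabolites.get_by_id(subnetwork.target_id): -1.0})
    cbm.reactions.get_by_id(sid).bounds = (demand, demand)
    if directionality_bounds:
        for rid, (lb, ub) in directionality_bounds.items():
            if rid in cbm.reactions:
                rxn = cbm.reactions.get_by_id(rid)
                rxn.bounds = (max(rxn.lower_bound, lb), min(rxn.upper_bound, ub))
    expr = sum(cbm.reactions.get_by_id(rid).forward_variable
               + cbm.reactions.get_by_id(rid).reverse_variable
               for rid in subnetwork.reactions) if subnetwork.reactions else 0
    cbm.objective = cbm.problem.Objective(expr, direction="min")
    value = cbm.slim_optimize(error_value=float("nan"))
    if cbm.solver.status != "optimal":
        raise ThermoInfeasibleError(
            f"net-flux minimization infeasible for subnetwork of "
            f"{subnetwork.target_id} (size {subnetwork.size})")
    fluxes = {r.id: r.flux for r in cbm.reactions}
    return FluxDistribution(fluxes, float(value), demand)


def _rationalize(x: float, cap: int = LUMP_DENOMINATOR_CAP,
                 tol: float = COEFF_DROP_TOL):
    frac = Fraction(x).limit_denominator(cap)
    if abs(float(frac) - x) <= tol:
        return frac
    return float(f"{x:.9g}")


def build_lump(subnetwork: Subnetwork, flux: FluxDistribution,
               model: MetabolicModel, partition: CorePartition,
               provenance: list[int] | None = None) -> LumpedReaction:
    """Sum the subnetwork columns weighted by flux, normalized to +1 target.

    Coefficients below tolerance are dropped; the rest are snapped to
    small rationals (falling back to 9-significant-digit floats) so that
    exact elemental cancellation survives the float LP.  A non-core
    intermediate surviving cleanup means the flux distribution was not
    steady for the subnetwork alone and raises
    :class:`LumpingResidueError`.
    """
    if not subnetwork.reactions:
        raise ValueError(
            f"target {subnetwork.target_id} is producible by the core alone; "
            "no lumped reaction is needed for an empty subnetwork")
    raw: dict[str, float] = {}
    for rid in subnetwork.reactions:
        v = flux.values.get(rid, 0.0)
        if abs(v) < SLACK_FLUX_TOL:
            log.warning("subnetwork member %s carries ~zero flux "
                        "(|v|=%.2e): solver slack", rid, abs(v))
            continue
        for met, coeff in model.reaction(rid).stoichiometry.items():
            raw[met] = raw.get(met, 0.0) + float(coeff) * v

    drained = model.drained_metabolites()
    stoich: dict[str, Fraction | float] = {}
    for met, total in raw.items():
        per_target = total / flux.demand
        if abs(per_target) < COEFF_DROP_TOL:
            continue
        if (met not in partition.core_metabolites
                and met != subnetwork.target_id and met not in drained):
            raise LumpingResidueError(
                f"non-core intermediate {met!r} survives lumping with "
                f"coefficient {per_target:.3e} (subnetwork of "
                f"{subnetwork.target_id})")
        stoich[met] = _rationalize(per_target)
    stoich[subnetwork.target_id] = Fraction(1)
    return LumpedReaction(subnetwork.target_id, stoich,
                          provenance=list(provenance or [subnetwork.rank]))


def lump_subnetwork(model: MetabolicModel, partition: CorePartition,
                    subnetwork: Subnetwork, demand: float,
                    directionality_bounds: dict | None = None,
                    check_degeneracy: bool = False,
                    seed: int = 0) -> LumpedReaction:
    """Convenience pipeline: L1 minimization, lumping, elemental audit.

    With ``check_degeneracy``, the L1 problem is re-solved with a tiny
    seeded jitter on the objective weights; a different resulting lump
    flags ``degenerate=True``.
    """
    flux = minimize_net_flux(model, partition, subnetwork, demand,
                             directionality_bounds)
    lump = build_lump(subnetwork, flux, model, partition)
    lump.balance_report = audit_elemental_balance(lump, model)
    if check_degeneracy and subnetwork.reactions:
        rng = random.Random(seed)
        weights = {rid: 1.0 + 1e-7 * rng.random()
                   for rid in subnetwork.reactions}
        jittered = _jittered_net_flux(model, partition, subnetwork, demand,
                                      weights, directionality_bounds)
        if jittered is not None:
            alt = build_lump(subnetwork, jittered, model, partition)
            if not lumps_equal(lump, alt):
                lump.degenerate = True
    return lump


def _jittered_net_flux(model, partition, subnetwork, demand, weights,
                       directionality_bounds):
    try:
        rxn_ids = sorted(partition.ungated_reactions | set(subnetwork.reactions))
        cbm = to_cobra(model, rxn_ids)
        sid = sink_id_for(subnetwork.target_id)
        if sid not in cbm.reactions:
            import cobra
            sink = cobra.Reaction(sid)
            cbm.add_reactions([sink])
            sink.add_metabolites(
                {cbm.metabolites.get_by_id(subnetwork.target_id): -1.0})
        cbm.reactions.get_by_id(sid).bounds = (demand, demand)
        if directionality_bounds:
            for rid, (lb, ub) in directionality_bounds.items():
                if rid in cbm.reactions:
                    rxn = cbm.reactions.get_by_id(rid)
                    rxn.bounds = (max(rxn.lower_bound, lb),
                                  min(rxn.upper_bound, ub))
        expr = sum(w * (cbm.reactions.get_by_id(rid).forward_variable
                        + cbm.reactions.get_by_id(rid).reverse_variable)
                   for rid, w in weights.items())
        cbm.objective = cbm.problem.Objective(expr, direction="min")
        cbm.slim_optimize(error_value=float("nan"))
        if cbm.solver.status != "optimal":
            return None
        return FluxDistribution({r.id: r.flux for r in cbm.reactions},
                                0.0, demand)
    except Exception:
        return None


def audit_elemental_balance(lump: LumpedReaction,
                            model: MetabolicModel) -> dict:
    """Residual of every audited element (and charge) of the lump.

    ``residual(e) = sum_m coeff(m) * atoms(e, m)``; exact when all
    coefficients are rational.  Participants without formulas are reported
    under the key ``"unaudited"`` (a list) rather than audited.
    """
    residual: dict[str, Fraction | float] = {}
    unaudited: list[str] = []
    audit_charge = True
    for met_id, coeff in lump.stoichiometry.items():
        met = model.metabolite(met_id)
        if met.formula is None:
            unaudited.append(met_id)
            continue
        for el, n in met.formula.items():
            residual[el] = residual.get(el, Fraction(0)) + coeff * n
        if met.charge is None:
            audit_charge = False
        else:
            residual["charge"] = residual.get("charge", Fraction(0)) + coeff * met.charge
    if not audit_charge:
        residual.pop("charge", None)
    report = dict(residual)
    if unaudited:
        report["unaudited"] = sorted(unaudited)
    return report


def lumps_equal(a: LumpedReaction, b: LumpedReaction,
                tol: float = COEFF_DROP_TOL) -> bool:
    if a.target_id != b.target_id:
        return False
    if set(a.stoichiometry) != set(b.stoichiometry):
        return False
    return all(abs(float(a.stoichiometry[m]) - float(b.stoichiometry[m])) <= tol
               for m in a.stoichiometry)


def dedupe_lumps(lumps) -> list[LumpedReaction]:
    """Collapse identical lumps (same participants/coefficients), merging
    provenance; output ordered by first occurrence."""
    unique: list[LumpedReaction] = []
    for lump in lumps:
        for kept in unique:
            if lumps_equal(kept, lump):
                kept.provenance = list(dict.fromkeys(
                    kept.provenance + lump.provenance))
                break
        else:
            unique.append(lump)
    return unique
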