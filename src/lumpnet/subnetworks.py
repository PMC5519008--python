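"""Minimal-subnetwork MILP and integer-cut enumeration of alternatives.

For a target metabolite j with synthesis demand n_j * mu_max, the MILP

    maximize   sum_i z_i          over non-core reactions i
    subject to S.v = 0
               v_sink,j >= demand
               F_i + B_i + C z_i <= C     (gating)

closes as many non-core reactions as possible; the open gates
``{i : z_i = 0}`` form the smallest subnetwork able to synthesize the
target from the core and the medium.  Alternatives are enumerated by
appending the integer cut ``sum_{k in subnetwork} z_k >= 1`` after each
solution, which forces at least one different reaction in the next one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import BlockedTargetError, SolverTimeoutError
from .gem_io import sink_id_for
from .model import MetabolicModel, to_cobra
from .partition import CorePartition, SplitGatedModel

log = logging.getLogger(__name__)

#: Fallback absolute demand (flux units) for targets outside the biomass.
FALLBACK_DEMAND = 1e-3

#: Relative slack accepted on the demand constraint during verification.
DEMAND_TOL = 1e-6

INTEGRALITY_TOL = 1e-6


@dataclass
class SubnetworkProblem:
    """One target's minimal-subnetwork MILP, built on a gated model."""

    gated: SplitGatedModel
    target_id: str
    sink_id: str
    demand: float


@dataclass
class Subnetwork:
    """A set of non-core reactions that, with the core, makes the target."""

    target_id: str
    reactions: frozenset[str]
    metabolites: frozenset[str]
    rank: int = 0

    @property
    def size(self) -> int:
        return len(self.reactions)


@dataclass
class EnumerationResult:
    subnetworks: list[Subnetwork]
    truncated: bool = False
    s_min: int | None = None

    def __iter__(self):
        return iter(self.subnetworks)

    def __len__(self):
        return len(self.subnetworks)


def demand_for_target(n_j, mu: float, fallback: float = FALLBACK_DEMAND) -> float:
    """Synthesis demand n_j * mu_max; fallback for non-biomass targets."""
    if n_j is None or mu is None:
        return fallback
    d = float(n_j) * float(mu)
    return d if d > 0 else fallback


def build_problem(gated: SplitGatedModel, target_id: str,
                  demand: float) -> SubnetworkProblem:
    """Attach (or reuse) the target's sink and fix v_sink >= demand.

    A gated model can be reused across targets: any sink configured by a
    previous call is restored to its original state first, so one
    target's demand never leaks into another's subnetworks.
    """
    if demand <= 0:
        raise ValueError(f"demand must be > 0, got {demand}")
    cbm = gated.cobra_model
    gated.source.metabolite(target_id)  # raises for unknown targets
    sid = sink_id_for(target_id)
    # undo the previous target's sink configuration
    state = getattr(gated, "_sink_state", {})
    for old_sid, (bounds, had_gate) in state.items():
        cbm.reactions.get_by_id(old_sid).bounds = bounds
        if had_gate:
            gated.z[old_sid].ub = 1
    state.clear()
    gated._sink_state = state
    if sid in cbm.reactions:
        sink = cbm.reactions.get_by_id(sid)
    else:
        import cobra
        if target_id not in cbm.metabolites:
            # declared but untouched by any reaction: the sink makes the
            # MILP infeasible and the target reports as blocked
            met = gated.source.metabolite(target_id)
            cbm.add_metabolites([cobra.Metabolite(
                target_id, compartment=met.compartment or "c")])
        sink = cobra.Reaction(sid)
        cbm.add_reactions([sink])
        sink.add_metabolites({cbm.metabolites.get_by_id(target_id): -1.0})
        sink.bounds = (0.0, 0.0)
    state[sid] = (sink.bounds, sid in gated.z)
    sink.bounds = (demand, max(1000.0, demand))
    if sid in gated.z:
        # the sink is problem infrastructure, not a subnetwork candidate:
        # keep its gate open for the duration of this problem
        gated.z[sid].ub = 0
    return SubnetworkProblem(gated, target_id, sid, demand)


def _solve_milp(problem: SubnetworkProblem, timeout: float | None):
    cbm = problem.gated.cobra_model
    if timeout is not None:
        cbm.solver.configuration.timeout = int(timeout)
    value = cbm.slim_optimize(error_value=float("nan"))
    return cbm.solver.status, value


def _extract(problem: SubnetworkProblem, rank: int) -> Subnetwork:
    gated = problem.gated
    open_gates = {rid for rid, z in gated.z.items()
                  if z.primal < 0.5 and rid != problem.sink_id}
    mets = gated.source.species_of(
        r for r in open_gates if gated.source.has_reaction(r))
    return Subnetwork(problem.target_id, frozenset(open_gates),
                      frozenset(mets), rank)


def find_min_subnetwork(problem: SubnetworkProblem,
                        timeout: float | None = None,
                        reverify: bool = True) -> Subnetwork:
    """Solve the MILP once and return the smallest subnetwork.

    Raises :class:`BlockedTargetError` when no binary assignment admits the
    demand, and :class:`SolverTimeoutError` on hitting the time limit.
    """
    gated = problem.gated
    cbm = gated.cobra_model
    cbm.objective = cbm.problem.Objective(
        sum(gated.z.values()), direction="max")
    status, value = _solve_milp(problem, timeout)
    if status == "infeasible":
        raise BlockedTargetError(problem.target_id)
    if status != "optimal":
        raise SolverTimeoutError(
            f"MILP for {problem.target_id} ended with status {status!r}")
    sub = _extract(problem, rank=0)
    n_candidates = gated.n_binaries - (1 if problem.sink_id in gated.z else 0)
    assert sub.size == n_candidates - round(value), \
        "subnetwork size inconsistent with MILP objective"
    if reverify and not verify_subnetwork(gated.source, gated.partition,
                                          sub.reactions, problem.target_id,
                                          problem.demand):
        raise AssertionError(
            f"LP re-verification failed for {problem.target_id} subnetwork")
    return sub


def enumerate_alternatives(problem: SubnetworkProblem,
                           mode: str = "minimal-only",
                           size_cap: int | None = None,
                           max_count: int = 1000,
                           timeout: float | None = None) -> EnumerationResult:
    """Enumerate alternative subnetworks with integer cuts.

    ``minimal-only`` stops as soon as the optimum grows beyond S_min;
    ``up-to-size`` keeps going until the size exceeds ``size_cap``.
    Solutions are pairwise distinct as sets and ordered by
    (size, discovery order).  Discovery order within one size class is
    solver-dependent; the *set* of minimal subnetworks is deterministic.
    """
    if mode not in {"minimal-only", "up-to-size"}:
        raise ValueError(f"unknown mode {mode!r}")
    gated = problem.gated
    cbm = gated.cobra_model
    cuts = []
    found: list[Subnetwork] = []
    truncated = False
    s_min: int | None = None
    try:
        first = find_min_subnetwork(problem, timeout=timeout)
        s_min = first.size
        cap = s_min if mode == "minimal-only" else (
            size_cap if size_cap is not None else s_min)
        found.append(first)
        while len(found) < max_count:
            last = found[-1]
            if not last.reactions:
                break  # empty subnetwork: the unique (core-only) solution
            cut = cbm.problem.Constraint(
                sum(gated.z[rid] for rid in last.reactions), lb=1,
                name=f"intcut__{len(cuts)}")
            cbm.add_cons_vars([cut])
            cuts.append(cut)
            status, value = _solve_milp(problem, timeout)
            if status == "infeasible":
                break
            if status != "optimal":
                raise SolverTimeoutError(
                    f"enumeration for {problem.target_id} ended with "
                    f"status {status!r}", incumbent=found)
            nxt = _extract(problem, rank=len(found))
            if nxt.size > cap:
                break
            found.append(nxt)
        else:
            truncated = True
            log.info("enumeration for %s truncated at max_count=%d",
                     problem.target_id, max_count)
    except BlockedTargetError:
        raise
    finally:
        if cuts:
            cbm.remove_cons_vars(cuts)
    found.sort(key=lambda s: (s.size, s.rank))
    return EnumerationResult(found, truncated, s_min)


def verify_subnetwork(model: MetabolicModel, partition: CorePartition,
                      reactions, target_id: str, demand: float,
                      check_minimality: bool = False) -> bool:
    """LP check that core + subnetwork admits v_sink >= demand.

    With ``check_minimality``, additionally require that deleting any
    single subnetwork reaction makes the demand unreachable.
    """
    reactions = set(reactions)
    rxn_ids = sorted(partition.ungated_reactions | reactions)
    cbm = to_cobra(model, rxn_ids)
    sid = sink_id_for(target_id)
    if sid not in cbm.reactions:
        if target_id not in cbm.metabolites:
            return False
        import cobra
        sink = cobra.Reaction(sid)
        cbm.add_reactions([sink])
        sink.add_metabolites({cbm.metabolites.get_by_id(target_id): -1.0})
    sink = cbm.reactions.get_by_id(sid)
    sink.bounds = (0.0, max(1000.0, demand))
    cbm.objective = sid
    threshold = demand * (1 - DEMAND_TOL) - 1e-9

    def max_sink() -> float:
        v = cbm.slim_optimize(error_value=float("nan"))
        return v if cbm.solver.status == "optimal" else float("-inf")

    if max_sink() < threshold:
        return False
    if check_minimality:
        for rid in sorted(reactions):
            rxn = cbm.reactions.get_by_id(rid)
            saved = rxn.bounds
            rxn.bounds = (0.0, 0.0)
            still_ok = max_sink() >= threshold
            rxn.bounds = saved
            if still_ok:
                return False
    return True
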