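"""Parameterized toy GEMs with planted minimal subnetworks, plus a
brute-force oracle.

The generator emits small models whose ground truth is known by
construction: a reversible core chain fed by a single carbon source, and
for each target one or more disjoint linear synthesis paths of planted
length.  Optional "balancer" steps shed a side metabolite that only a
dedicated balancing reaction can return to the core, reproducing the
branched-subnetwork topology that mass balance forces on real synthesis
routes: the minimal subnetwork is then the path plus all its balancers.
Every metabolite carries a synthetic formula (an integer multiple of one
base composition), so all reactions balance exactly and lumps can be
audited end to end.

The oracle enumerates non-core reaction subsets by increasing cardinality
and LP-tests each one (scipy/HiGHS, independent of the GLPK MILP route),
returning every feasible set of the minimum cardinality.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import lil_matrix

from .errors import BlockedTargetError
from .gem_io import sink_id_for
from .model import MetabolicModel, Metabolite, Reaction
from .partition import CorePartition, define_core

#: Demand-side tolerance mirroring the MILP verification threshold.
_DEMAND_TOL = 1e-6


@dataclass
class ToySpec:
    """Recipe for one toy GEM; the seed fully determines the output."""

    n_core_reactions: int = 4
    planted_paths: tuple[tuple[int, int], ...] = ((3, 2),)  # (length, count)
    branch_balancers: int = 0
    element_palette: tuple[str, ...] = ("C", "H", "O")
    seed: int = 0
    n_targets: int = 1
    n_decoys: int = 2
    uptake: float = 10.0
    demand: float = 1.0
    with_biomass: bool = False
    biomass_coefficient: float = 0.1  # mmol of each target per gDW
    core_target: bool = False

    def __post_init__(self):
        if self.n_core_reactions < 1:
            raise ValueError("need at least one core reaction")
        for length, count in self.planted_paths:
            if length < 1 or count < 1:
                raise ValueError("path lengths and counts must be >= 1")
            if self.branch_balancers > length - 1:
                raise ValueError(
                    f"{self.branch_balancers} balancers do not fit in a "
                    f"{length}-step path (need length >= balancers + 1)")


@dataclass
class ToyFixture:
    model: MetabolicModel
    partition: CorePartition
    #: target id -> {"s_min": int, "min_sets": set of frozensets,
    #:               "lumps": list of stoichiometry dicts}
    ground_truth: dict[str, dict]
    spec: ToySpec

    @property
    def targets(self) -> list[str]:
        return sorted(self.ground_truth)


def _base_formula(palette, rng) -> dict[str, int]:
    formula = {}
    for el in palette:
        formula[el] = 6 if el == "C" else rng.randint(2, 12)
    if "C" not in formula:
        formula["C"] = 6
    return formula


def make_toy_gem(spec: ToySpec, certify: bool = True) -> ToyFixture:
    """Generate a toy GEM with planted cores and certified ground truth.

    With ``certify`` the constructed ground truth of the first target is
    re-verified against :func:`brute_force_min_subnetworks`; a mismatch is
    a generation error.
    """
    rng = random.Random(spec.seed)
    base = _base_formula(spec.element_palette, rng)

    def formula(mult: int) -> dict[str, int]:
        return {el: n * mult for el, n in base.items()}

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def met(mid, mult=1):
        mets.append(Metabolite(mid, compartment="c", formula=formula(mult),
                               charge=0))
        return mid

    n_chain = spec.n_core_reactions
    chain = [met(f"M{i}") for i in range(n_chain + 1)]
    core_ids = []
    for i in range(n_chain):
        rid = f"CORE{i}"
        rxns.append(Reaction(rid, {chain[i]: Fraction(-1),
                                   chain[i + 1]: Fraction(1)},
                             -1000.0, 1000.0, subsystem="core-chain"))
        core_ids.append(rid)
    ex_id = "EX_M0"
    rxns.append(Reaction(ex_id, {chain[0]: Fraction(-1)},
                         -spec.uptake, 1000.0, subsystem="exchange"))
    core_ids.append(ex_id)

    ground_truth: dict[str, dict] = {}
    b = spec.branch_balancers
    for t in range(spec.n_targets):
        tid = f"TGT{t}"
        if spec.core_target:
            tid = rng.choice(chain)
            ground_truth[tid] = {"s_min": 0, "min_sets": {frozenset()},
                                 "lumps": []}
            continue
        met(tid)
        planted: list[tuple[int, frozenset, dict]] = []
        for g, (length, count) in enumerate(spec.planted_paths):
            for p in range(count):
                tag = f"{t}_{g}_{p}"
                anchor = rng.choice(chain)
                recycle = rng.choice(chain)
                path_rxns: list[str] = []
                nodes = [f"X{tag}_{s}" for s in range(1, length)] + [tid]
                prev, prev_mult = anchor, 1 + b
                shed = 0
                for s, node in enumerate(nodes):
                    if s == 0:
                        stoich = {anchor: Fraction(-(1 + b)),
                                  node: Fraction(1)}
                        mult = 1 + b
                    elif shed < b:
                        # shed one side metabolite; only BAL can consume it
                        y_id = met(f"Y{tag}_{shed}")
                        stoich = {prev: Fraction(-1), node: Fraction(1),
                                  y_id: Fraction(1)}
                        bal_id = f"BAL{tag}_{shed}"
                        rxns.append(Reaction(
                            bal_id, {y_id: Fraction(-1), recycle: Fraction(1)},
                            0.0, 1000.0, subsystem="balancer"))
                        path_rxns.append(bal_id)
                        shed += 1
                        mult = prev_mult - 1
                    else:
                        stoich = {prev: Fraction(-1), node: Fraction(1)}
                        mult = prev_mult
                    if node != tid:
                        met(node, mult)
                    rid = f"P{tag}_{s}"
                    rxns.append(Reaction(rid, stoich, 0.0, 1000.0,
                                         subsystem="planted-path"))
                    path_rxns.append(rid)
                    prev, prev_mult = node, mult
                assert prev_mult == 1 and shed == b, "balancer bookkeeping"
                lump = {anchor: Fraction(-(1 + b)), tid: Fraction(1)}
                if b:
                    lump[recycle] = lump.get(recycle, Fraction(0)) + b
                lump = {m: c for m, c in lump.items() if c != 0}
                planted.append((len(path_rxns), frozenset(path_rxns), lump))
        s_min = min(size for size, _, _ in planted)
        ground_truth[tid] = {
            "s_min": s_min,
            "min_sets": {rs for size, rs, _ in planted if size == s_min},
            "lumps": [dict(l) for size, _, l in planted if size == s_min],
        }

    for d in range(spec.n_decoys):
        src = rng.choice(chain)
        if d % 2 == 0:
            dead = met(f"D{d}")
            rxns.append(Reaction(f"DEC{d}", {src: Fraction(-1),
                                             dead: Fraction(1)},
                                 0.0, 1000.0, subsystem="decoy"))
        else:
            dst = rng.choice([m for m in chain if m != src])
            rxns.append(Reaction(f"DEC{d}", {src: Fraction(-1),
                                             dst: Fraction(1)},
                                 0.0, 1000.0, subsystem="decoy"))

    objective = None
    if spec.with_biomass:
        stoich = {tid: Fraction(-spec.biomass_coefficient).limit_denominator(1000)
                  for tid in ground_truth}
        rxns.append(Reaction("BIOMASS", stoich, 0.0, 1000.0,
                             subsystem="biomass"))
        objective = "BIOMASS"

    model = MetabolicModel(mets, rxns, objective, {ex_id: spec.uptake},
                           id=f"toy_seed{spec.seed}")
    partition = define_core(model, core_ids)
    fixture = ToyFixture(model, partition, ground_truth, spec)

    if certify:
        tid = fixture.targets[0]
        truth = ground_truth[tid]
        oracle = brute_force_min_subnetworks(
            model, partition, tid, spec.demand)
        if oracle != truth["min_sets"]:
            raise ValueError(
                f"toy generation error (seed {spec.seed}): oracle disagrees "
                f"with planted ground truth for {tid}")
    return fixture


def brute_force_min_subnetworks(model: MetabolicModel,
                                partition: CorePartition, target_id: str,
                                demand: float,
                                max_size: int | None = None) -> set[frozenset]:
    """All minimum-cardinality non-core reaction sets meeting the demand.

    Exhaustive subset enumeration by increasing cardinality with an LP
    feasibility test per subset (HiGHS); stops at the first feasible size.
    Every returned set is inclusion-minimal, since all proper subsets are
    smaller than the minimum cardinality.  Intended for |R^ncGEM| <= ~20.
    """
    sink_id = sink_id_for(target_id)
    candidates = sorted(partition.noncore_reactions - {sink_id})
    if max_size is None:
        max_size = len(candidates)

    ungated = sorted(partition.ungated_reactions)
    has_sink = model.has_reaction(sink_id)
    if has_sink and sink_id not in set(ungated):
        ungated.append(sink_id)  # the target's own sink is infrastructure
    rxn_ids = ungated + candidates
    n_rxn = len(rxn_ids) + (0 if has_sink else 1)
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    S = lil_matrix((len(met_index), n_rxn))
    bounds = []
    for j, rid in enumerate(rxn_ids):
        rxn = model.reaction(rid)
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], j] = float(coeff)
        if rid == sink_id:
            bounds.append((0.0, demand))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    if has_sink:
        sink_col = rxn_ids.index(sink_id)
    else:
        sink_col = n_rxn - 1
        S[met_index[target_id], sink_col] = -1.0
        bounds.append((0.0, demand))
    S = S.tocsr()
    c = np.zeros(n_rxn)
    c[sink_col] = -1.0
    cand_col = {rid: len(ungated) + k for k, rid in enumerate(candidates)}
    threshold = demand * (1 - _DEMAND_TOL) - 1e-9

    def feasible(subset) -> bool:
        bnds = list(bounds)
        off = set(candidates) - set(subset)
        for rid in off:
            bnds[cand_col[rid]] = (0.0, 0.0)
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bnds,
                      method="highs")
        return res.status == 0 and -res.fun >= threshold

    # pruning: unless the core itself can make the target, any feasible
    # subset must contain a reaction able to produce it
    producers = set()
    for rid in candidates:
        rxn = model.reaction(rid)
        coeff = rxn.stoichiometry.get(target_id)
        if coeff is None:
            continue
        if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
            producers.add(rid)
    core_touches = any(
        target_id in model.reaction(rid).stoichiometry
        for rid in partition.ungated_reactions)

    for k in range(0, max_size + 1):
        hits = {frozenset(sub) for sub in itertools.combinations(candidates, k)
                if (core_touches or set(sub) & producers or k == 0)
                and feasible(sub)}
        if hits:
            return hits
    raise BlockedTargetError(target_id)


def make_yield_demo(uptake: float = 10.0):
    """Hand-derivable yield fixture: one carbon-conserving lump (yield 1)
    and one lump losing a CO2 per 6-carbon target (yield 6/7).

    Returns ``(model, partition, lumps)`` where ``lumps`` is a list of two
    stoichiometry dicts for the same target, suitable for
    :func:`lumpnet.yields.build_mini_model`.
    """
    mets = [
        Metabolite("glc", formula={"C": 6, "H": 12, "O": 6}, charge=0),
        Metabolite("tgt", formula={"C": 6, "H": 14, "O": 5}, charge=0),
        Metabolite("co2", formula={"C": 1, "O": 2}, charge=0),
        Metabolite("h2o", formula={"H": 2, "O": 1}, charge=0),
        Metabolite("o2", formula={"O": 2}, charge=0),
    ]
    rxns = [
        Reaction("EX_glc", {"glc": Fraction(-1)}, -uptake, 1000.0),
        Reaction("EX_h2o", {"h2o": Fraction(-1)}, -1000.0, 1000.0),
        Reaction("EX_o2", {"o2": Fraction(-1)}, 0.0, 1000.0),
        Reaction("EX_co2", {"co2": Fraction(-1)}, 0.0, 1000.0),
    ]
    model = MetabolicModel(mets, rxns, None, {"EX_glc": uptake},
                           id="yield_demo")
    partition = define_core(model, [r.id for r in rxns])
    lump_loss = {"glc": Fraction(-7, 6), "co2": Fraction(1),
                 "tgt": Fraction(1)}
    lump_conserving = {"glc": Fraction(-1), "h2o": Fraction(-1),
                       "o2": Fraction(1), "tgt": Fraction(1)}
    return model, partition, [lump_conserving, lump_loss]
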