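from fractions import Fraction

import pytest

from lumpnet.errors import LumpingResidueError
from lumpnet.lumping import (FluxDistribution, LumpedReaction,
                             audit_elemental_balance, build_lump, dedupe_lumps,
                             lump_subnetwork, lumps_equal, minimize_net_flux)
from lumpnet.partition import split_and_gate
from lumpnet.subnetworks import Subnetwork, build_problem, find_min_subnetwork
from lumpnet.toys import ToySpec, make_toy_gem, make_yield_demo

DEMAND = 1.0


def test_single_reaction_subnetwork_lumps_to_itself():
    fx = make_toy_gem(ToySpec(seed=31, planted_paths=((1, 1),),
                              n_decoys=1), certify=False)
    target = fx.targets[0]
    gated = split_and_gate(fx.model, fx.partition)
    sub = find_min_subnetwork(build_problem(gated, target, DEMAND))
    assert sub.size == 1
    flux = minimize_net_flux(fx.model, fx.partition, sub, DEMAND)
    (rid,) = sub.reactions
    assert flux.values[rid] == pytest.approx(DEMAND)
    assert flux.objective_value == pytest.approx(DEMAND)
    lump = build_lump(sub, flux, fx.model, fx.partition)
    normalized = {m: c for m, c in fx.model.reaction(rid).stoichiometry.items()}
    assert lump.stoichiometry == normalized


def test_diamond_flux_confined_to_one_route(diamond):
    model, partition = diamond
    sub = Subnetwork("T", frozenset(["R_up1", "R_dn1", "R_up2", "R_dn2"]),
                     frozenset(["A", "X1", "X2", "T"]))
    flux = minimize_net_flux(model, partition, sub, DEMAND)
    # L1 optimum: 2*demand total, one route carries everything
    assert flux.objective_value == pytest.approx(2 * DEMAND, abs=1e-9)
    route1 = abs(flux.values["R_up1"]) + abs(flux.values["R_dn1"])
    route2 = abs(flux.values["R_up2"]) + abs(flux.values["R_dn2"])
    assert {round(route1, 9), round(route2, 9)} == {0.0, 2 * DEMAND}
    lump = build_lump(sub, flux, model, partition)
    assert lump.stoichiometry == {"A": Fraction(-1), "T": Fraction(1)}


def test_lump_is_scale_invariant(balancer_fixture):
    fx = balancer_fixture
    target = fx.targets[0]
    gated = split_and_gate(fx.model, fx.partition)
    sub = find_min_subnetwork(build_problem(gated, target, DEMAND))
    lump1 = lump_subnetwork(fx.model, fx.partition, sub, DEMAND)
    lump2 = lump_subnetwork(fx.model, fx.partition, sub, 2 * DEMAND)
    assert lump1.stoichiometry == lump2.stoichiometry


def test_lump_participants_are_core_target_or_drained(balancer_fixture):
    fx = balancer_fixture
    target = fx.targets[0]
    gated = split_and_gate(fx.model, fx.partition)
    sub = find_min_subnetwork(build_problem(gated, target, DEMAND))
    lump = lump_subnetwork(fx.model, fx.partition, sub, DEMAND)
    drained = fx.model.drained_metabolites()
    for met in lump.stoichiometry:
        assert (met in fx.partition.core_metabolites or met == target
                or met in drained)
    assert all(v == 0 for k, v in lump.balance_report.items()
               if k != "unaudited")


def test_unsteady_flux_distribution_raises_residue_error(balancer_fixture):
    fx = balancer_fixture
    target = fx.targets[0]
    gated = split_and_gate(fx.model, fx.partition)
    sub = find_min_subnetwork(build_problem(gated, target, DEMAND))
    flux = minimize_net_flux(fx.model, fx.partition, sub, DEMAND)
    rid = next(r for r in sub.reactions if not r.startswith("BAL"))
    tampered = dict(flux.values)
    tampered[rid] *= 0.5  # breaks steady state inside the subnetwork
    with pytest.raises(LumpingResidueError):
        build_lump(sub, FluxDistribution(tampered, flux.objective_value,
                                         DEMAND),
                   fx.model, fx.partition)


def test_audit_flags_missing_water():
    model, _, stoichs = make_yield_demo()
    balanced = LumpedReaction("tgt", dict(stoichs[0]))
    assert audit_elemental_balance(balanced, model) == {
        "C": 0, "H": 0, "O": 0, "charge": 0}
    corrupted = {m: c for m, c in stoichs[0].items() if m != "h2o"}
    report = audit_elemental_balance(LumpedReaction("tgt", corrupted), model)
    # the dropped reactant leaves one water's worth of excess product atoms
    assert report["H"] == 2 and report["O"] == 1 and report["C"] == 0


def test_audit_empty_lump_is_trivially_balanced(balancer_fixture):
    report = audit_elemental_balance(LumpedReaction("x", {}),
                                     balancer_fixture.model)
    assert all(v == 0 for v in report.values())


def test_dedupe_merges_identical_and_keeps_distinct():
    a = LumpedReaction("T", {"A": Fraction(-1), "T": Fraction(1)},
                       provenance=[0])
    b = LumpedReaction("T", {"A": Fraction(-1), "T": Fraction(1)},
                       provenance=[1])
    c = LumpedReaction("T", {"A": Fraction(-2), "T": Fraction(1)},
                       provenance=[2])
    out = dedupe_lumps([a, b, c])
    assert len(out) == 2
    assert out[0].provenance == [0, 1]
    assert out[1].provenance == [2]
    assert dedupe_lumps([c]) == [c]
    # a sub-tolerance coefficient wobble still counts as the same lump
    d = LumpedReaction("T", {"A": -1.0 + 5e-7, "T": Fraction(1)})
    assert lumps_equal(a, d)


def test_equation_rendering_sorted_sides():
    lump = LumpedReaction("T", {"B": Fraction(-2), "A": Fraction(-1),
                                "T": Fraction(1), "C": Fraction(1, 2)})
    assert lump.equation() == "A + 2 B -> 1/2 C + T"
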