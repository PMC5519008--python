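from fractions import Fraction

import pytest

from lumpnet.errors import LookupError_, ParameterError
from lumpnet.fba import fba
from lumpnet.model import MetabolicModel, Metabolite, Reaction
from lumpnet.partition import (DEFAULT_BIG_M, default_carbon_cap, define_core,
                               split_and_gate)
from lumpnet.toys import ToySpec, make_toy_gem


def test_define_core_sets_and_complements(two_path_fixture):
    model, part = two_path_fixture.model, two_path_fixture.partition
    assert part.core_reactions | part.noncore_reactions | part.always_on == \
           set(model.reaction_ids)
    assert part.core_metabolites == model.species_of(part.core_reactions)
    assert part.noncore_metabolites == \
           set(model.metabolite_ids) - part.core_metabolites
    part.validate(model)


def test_define_core_with_all_reactions_leaves_no_noncore(two_path_fixture):
    model = two_path_fixture.model
    part = define_core(model, model.reaction_ids)
    assert part.noncore_reactions == set()
    assert part.core_metabolites == set(model.metabolite_ids)


def test_define_core_extra_metabolites_and_unknown_ids(two_path_fixture):
    model = two_path_fixture.model
    core = sorted(two_path_fixture.partition.core_reactions)
    target = two_path_fixture.targets[0]
    part = define_core(model, core, extra_core_metabolites=[target])
    assert target in part.core_metabolites
    assert target not in part.noncore_metabolites
    with pytest.raises(LookupError_) as err:
        define_core(model, core + ["NOPE"])
    assert "NOPE" in str(err.value)


def test_define_core_can_exempt_boundary_reactions(two_path_fixture):
    model = two_path_fixture.model
    enzymatic = [r for r in two_path_fixture.partition.core_reactions
                 if not model.reaction(r).is_boundary]
    part = define_core(model, enzymatic, gate_transports=False)
    assert "EX_M0" in part.always_on
    part.validate(model)


def test_gating_closes_and_opens_flux(two_path_fixture):
    model, part = two_path_fixture.model, two_path_fixture.partition
    gated = split_and_gate(model, part)
    assert gated.n_binaries == len(part.noncore_reactions)
    rid = sorted(part.noncore_reactions)[0]
    rxn = gated.cobra_model.reactions.get_by_id(rid)
    expr = rxn.forward_variable + rxn.reverse_variable
    gated.cobra_model.objective = gated.cobra_model.problem.Objective(
        expr, direction="max")
    z = gated.z[rid]
    z.lb, z.ub = 1, 1  # gate shut
    assert gated.cobra_model.slim_optimize() == pytest.approx(0.0, abs=1e-9)
    z.lb, z.ub = 0, 0  # gate open
    v = gated.cobra_model.slim_optimize()
    assert v <= gated.carbon_cap + 1e-6
    z.lb, z.ub = 0, 1


def test_splitting_preserves_fba_optimum():
    # biomass coefficient chosen so the optimum sits below the carbon cap:
    # open gates then impose no binding restriction beyond |v| <= C
    spec = ToySpec(seed=13, planted_paths=((2, 1),), n_targets=1,
                   with_biomass=True, biomass_coefficient=0.5)
    fx = make_toy_gem(spec, certify=False)
    mu_plain = fba(fx.model, "BIOMASS").objective_value
    assert mu_plain < 60.0  # sanity: below the C6-source cap
    gated = split_and_gate(fx.model, fx.partition)
    cbm = gated.cobra_model
    for z in gated.z.values():
        z.ub = 0  # every gate open: pure split model, fluxes capped at C
    cbm.objective = "BIOMASS"
    assert cbm.slim_optimize() == pytest.approx(mu_plain, abs=1e-9)


def test_open_gates_cap_fluxes_at_carbon_cap(two_path_fixture):
    # FVA-style check: with all gates open no gated reaction exceeds C,
    # and C admits every flux the medium allows
    model, part = two_path_fixture.model, two_path_fixture.partition
    gated = split_and_gate(model, part)
    cbm = gated.cobra_model
    for z in gated.z.values():
        z.ub = 0
    for rid in sorted(part.noncore_reactions):
        rxn = cbm.reactions.get_by_id(rid)
        cbm.objective = cbm.problem.Objective(
            rxn.forward_variable + rxn.reverse_variable, direction="max")
        assert cbm.slim_optimize() <= gated.carbon_cap + 1e-6


def test_default_carbon_cap_from_single_source(two_path_fixture):
    # C6 source at uptake 10 -> 60 carbon-atom flux units
    assert default_carbon_cap(two_path_fixture.model) == pytest.approx(60.0)


def test_default_carbon_cap_falls_back_on_multiple_sources():
    f = {"C": 3, "H": 6, "O": 3}
    mets = [Metabolite("a", formula=f), Metabolite("b", formula=f)]
    rxns = [Reaction("EX_a", {"a": Fraction(-1)}, -10, 1000),
            Reaction("EX_b", {"b": Fraction(-1)}, -5, 1000)]
    model = MetabolicModel(mets, rxns, None,
                           {"EX_a": 10.0, "EX_b": 5.0})
    assert default_carbon_cap(model) == DEFAULT_BIG_M


def test_nonpositive_carbon_cap_rejected(two_path_fixture):
    with pytest.raises(ParameterError):
        split_and_gate(two_path_fixture.model, two_path_fixture.partition,
                       carbon_cap=0.0)
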