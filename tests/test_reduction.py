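import pytest

from lumpnet.errors import AssemblyError
from lumpnet.fba import fba, mu_max
from lumpnet.lumping import dedupe_lumps, lump_subnetwork
from lumpnet.partition import split_and_gate
from lumpnet.reduction import (assemble_candidate_model,
                               select_minimal_lump_set, validate_growth,
                               write_selection_report)
from lumpnet.subnetworks import build_problem, enumerate_alternatives
from lumpnet.toys import ToySpec, make_toy_gem

DEMAND = 1.0


@pytest.fixture(scope="module")
def growth_toy():
    spec = ToySpec(seed=41, n_core_reactions=4, planted_paths=((2, 2),),
                   n_targets=2, n_decoys=2, with_biomass=True)
    fx = make_toy_gem(spec, certify=False)
    gated = split_and_gate(fx.model, fx.partition)
    lumps = []
    for target in fx.targets:
        problem = build_problem(gated, target, DEMAND)
        for sub in enumerate_alternatives(problem):
            lumps.append(lump_subnetwork(fx.model, fx.partition, sub, DEMAND))
    return fx, dedupe_lumps(lumps)


def test_candidate_model_reaction_count(growth_toy):
    fx, lumps = growth_toy
    candidate = assemble_candidate_model(fx.model, fx.partition, lumps,
                                         "BIOMASS")
    expected = (len(fx.partition.core_reactions)
                + len(fx.partition.always_on) + len(lumps) + 1)
    assert len(candidate.reactions) == expected
    assert candidate.objective_reaction_id == "BIOMASS"


def test_candidate_without_lumps_names_orphan_species(growth_toy):
    fx, _ = growth_toy
    with pytest.raises(AssemblyError) as err:
        assemble_candidate_model(fx.model, fx.partition, [], "BIOMASS")
    assert "TGT" in str(err.value)


def test_selection_keeps_one_of_each_redundant_pair(growth_toy):
    fx, lumps = growth_toy
    candidate = assemble_candidate_model(fx.model, fx.partition, lumps,
                                         "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    # one lump per target suffices at maximal growth
    assert len([r for r in reduced.model.reactions
                if r.id.startswith("LMP_")]) == len(fx.targets)
    targets_covered = {l.target_id for l in reduced.selected_lumps}
    assert targets_covered == set(fx.targets)


def test_reduced_growth_close_to_parent(growth_toy):
    fx, lumps = growth_toy
    mu_gem = mu_max(fx.model)
    candidate = assemble_candidate_model(fx.model, fx.partition, lumps,
                                         "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    mu_red = validate_growth(reduced)
    assert mu_red <= mu_gem + 1e-6
    assert (mu_gem - mu_red) / mu_gem < 0.05


def test_selected_lumps_carry_flux_and_are_necessary(growth_toy):
    fx, lumps = growth_toy
    candidate = assemble_candidate_model(fx.model, fx.partition, lumps,
                                         "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    res = fba(reduced.model, "BIOMASS", return_fluxes=True)
    lump_ids = [r.id for r in reduced.model.reactions
                if r.id.startswith("LMP_")]
    for rid in lump_ids:
        assert abs(res.fluxes[rid]) > 1e-9  # no dead selections
        rest = [r.id for r in reduced.model.reactions if r.id != rid]
        pruned = reduced.model.subnetwork_model(rest)
        pruned.objective_reaction_id = "BIOMASS"
        ko = fba(pruned, "BIOMASS")
        mu_ko = ko.objective_value if ko.ok else 0.0
        assert mu_ko < reduced.mu_at_medium * (1 - 1e-4)


def test_all_lumps_selected_when_none_redundant():
    spec = ToySpec(seed=43, planted_paths=((2, 1),), n_targets=2,
                   n_decoys=1, with_biomass=True)
    fx = make_toy_gem(spec, certify=False)
    gated = split_and_gate(fx.model, fx.partition)
    lumps = []
    for target in fx.targets:
        problem = build_problem(gated, target, DEMAND)
        sub = enumerate_alternatives(problem).subnetworks[0]
        lumps.append(lump_subnetwork(fx.model, fx.partition, sub, DEMAND))
    candidate = assemble_candidate_model(fx.model, fx.partition,
                                         dedupe_lumps(lumps), "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    assert len(reduced.selected_lumps) == len(fx.targets)


def test_selection_report_lists_all_lumps(tmp_path, growth_toy):
    fx, lumps = growth_toy
    candidate = assemble_candidate_model(fx.model, fx.partition, lumps,
                                         "BIOMASS")
    reduced = select_minimal_lump_set(candidate)
    out = tmp_path / "selection.tsv"
    write_selection_report(candidate, reduced, out)
    lines = out.read_text().strip().splitlines()
    assert lines[0] == "lump\tselected\tflux_at_optimum"
    assert len(lines) == 1 + len(lumps)
    assert sum(1 for l in lines[1:] if l.split("\t")[1] == "yes") == \
           len(fx.targets)
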