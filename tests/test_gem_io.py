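import json
from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lumpnet.errors import FormatError, LookupError_
from lumpnet.gem_io import (add_target_sinks, load_model, parse_biomass,
                            write_model)
from lumpnet.model import (MetabolicModel, Metabolite, Reaction,
                           format_formula, parse_formula)
from lumpnet.toys import ToySpec, make_toy_gem


def _stoich_map(model):
    return {r.id: dict(r.stoichiometry) for r in model.reactions}


def _bounds_map(model):
    return {r.id: (r.lower_bound, r.upper_bound) for r in model.reactions}


@pytest.mark.parametrize("suffix", ["json", "xml"])
def test_write_load_round_trip_preserves_model(tmp_path, suffix):
    fx = make_toy_gem(ToySpec(seed=4, branch_balancers=1,
                              planted_paths=((3, 1),)), certify=False)
    path = tmp_path / f"toy.{suffix}"
    write_model(fx.model, path)
    reloaded = load_model(path)
    assert _stoich_map(reloaded) == _stoich_map(fx.model)
    assert _bounds_map(reloaded) == _bounds_map(fx.model)
    assert {m.id: m.formula for m in reloaded.metabolites} == \
           {m.id: m.formula for m in fx.model.metabolites}


def test_load_unparsable_file_raises_format_error(tmp_path):
    bad = tmp_path / "bad.json"
    bad.write_text("{this is not json")
    with pytest.raises(FormatError):
        load_model(bad)
    with pytest.raises(FormatError):
        load_model(tmp_path / "missing.json")


def test_metabolite_without_formula_is_flagged_not_fatal(tmp_path):
    fx = make_toy_gem(ToySpec(seed=4), certify=False)
    path = tmp_path / "toy.json"
    write_model(fx.model, path)
    doc = json.loads(path.read_text())
    doc["metabolites"][0].pop("formula", None)
    stripped = doc["metabolites"][0]["id"]
    path.write_text(json.dumps(doc))
    model = load_model(path)
    assert stripped in model.unaudited_metabolites
    assert model.metabolite(stripped).formula is None


@given(st.dictionaries(
    st.sampled_from(["C", "H", "N", "O", "P", "S", "Fe", "Mg"]),
    st.integers(min_value=1, max_value=99), min_size=1, max_size=6))
def test_formula_format_parse_round_trip(composition):
    assert parse_formula(format_formula(composition)) == composition


def _model_with_biomass(stoich):
    mets = [Metabolite(m, compartment="c") for m in stoich]
    rxns = [Reaction("BIOMASS", {m: Fraction(c) for m, c in stoich.items()},
                     0.0, 1000.0)]
    return MetabolicModel(mets, rxns, "BIOMASS")


def test_parse_biomass_simple_demands_have_no_gam():
    model = _model_with_biomass({"A_c": -1, "B_c": -2})
    comp = parse_biomass(model)
    assert comp.gam_atp == 0 and comp.adenylate_imbalance == 0
    assert {(e.bbb_id, e.n_j, e.role) for e in comp.entries} == {
        ("A_c", 1, "consumed"), ("B_c", 2, "consumed")}


def test_parse_biomass_extracts_gam_and_adenylate_imbalance():
    # ATP consumption exceeds ADP production by 1.05: the matched 53.95
    # is growth-associated maintenance, the excess is de-novo adenylate
    # demand
    gam = Fraction("53.95")
    model = _model_with_biomass({
        "atp_c": -55, "adp_c": gam, "h2o_c": -gam, "pi_c": gam, "h_c": gam,
        "ala_c": Fraction(-1, 2), "ppi_c": Fraction(3, 4)})
    comp = parse_biomass(model)
    assert comp.gam_atp == gam
    assert comp.adenylate_imbalance == Fraction("1.05")
    roles = {e.bbb_id: (e.n_j, e.role) for e in comp.entries}
    assert roles["ala_c"] == (Fraction(1, 2), "consumed")
    assert roles["ppi_c"] == (Fraction(3, 4), "produced")
    assert "atp_c" not in roles  # fully assigned to GAM + imbalance


def test_parse_biomass_reconstruction_is_lossless():
    stoich = {"atp_c": Fraction(-54), "adp_c": Fraction("53.95"),
              "h2o_c": Fraction(-49), "pi_c": Fraction("53.95"),
              "h_c": Fraction("53.95"), "glu_c": Fraction(-3, 7),
              "ppi_c": Fraction(1, 3)}
    model = _model_with_biomass(stoich)
    comp = parse_biomass(model)
    assert comp.reconstruct() == stoich
    # H2O limits the matched hydrolysis here
    assert comp.gam_atp == 49


def test_parse_biomass_unknown_reaction_raises():
    model = _model_with_biomass({"A_c": -1})
    with pytest.raises(LookupError_):
        parse_biomass(model, "NOT_THERE")


def test_add_target_sinks_adds_irreversible_drains():
    fx = make_toy_gem(ToySpec(seed=4), certify=False)
    target = fx.targets[0]
    before = len(fx.model.reactions)
    out = add_target_sinks(fx.model, [target])
    assert len(out.reactions) == before + 1
    sink = out.reaction(f"sink_{target}")
    assert sink.stoichiometry == {target: Fraction(-1)}
    assert sink.lower_bound == 0 and sink.upper_bound == float("inf")
    # original untouched
    assert not fx.model.has_reaction(f"sink_{target}")


def test_add_target_sinks_empty_and_duplicate_handling():
    fx = make_toy_gem(ToySpec(seed=4), certify=False)
    assert len(add_target_sinks(fx.model, []).reactions) == \
           len(fx.model.reactions)
    target = fx.targets[0]
    once = add_target_sinks(fx.model, [target])
    twice = add_target_sinks(once, [target])
    assert twice.has_reaction(f"sink_{target}_1")
    with pytest.raises(LookupError_):
        add_target_sinks(fx.model, ["no_such_met"])
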