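import logging
from fractions import Fraction

import pytest
from hypothesis import settings

from lumpnet.model import MetabolicModel, Metabolite, Reaction
from lumpnet.partition import define_core
from lumpnet.toys import ToySpec, make_toy_gem

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

logging.getLogger("cobra").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def balancer_fixture():
    """Toy with one 3-step path plus one mandatory balancing reaction."""
    return make_toy_gem(ToySpec(seed=11, n_core_reactions=3,
                                planted_paths=((3, 1),), branch_balancers=1,
                                n_decoys=2))


@pytest.fixture(scope="session")
def two_path_fixture():
    """Toy with two disjoint planted 3-step paths of equal length."""
    return make_toy_gem(ToySpec(seed=5, n_core_reactions=4,
                                planted_paths=((3, 2),), branch_balancers=0,
                                n_decoys=2))


@pytest.fixture(scope="session")
def mixed_length_fixture():
    """Toy with one 2-step and one 3-step path to the same target."""
    return make_toy_gem(ToySpec(seed=8, n_core_reactions=4,
                                planted_paths=((2, 1), (3, 1)),
                                branch_balancers=0, n_decoys=2))


@pytest.fixture()
def diamond():
    """Two parallel 2-step routes from one core precursor to the target.

    Both routes together form the 'subnetwork'; an L1-minimal flux
    distribution must confine flux to a single route.
    """
    f = {"C": 6, "H": 12, "O": 6}
    mets = [Metabolite(m, formula=dict(f), charge=0)
            for m in ["A", "X1", "X2", "T"]]
    rxns = [
        Reaction("EX_A", {"A": Fraction(-1)}, -10.0, 1000.0),
        Reaction("R_up1", {"A": Fraction(-1), "X1": Fraction(1)}, 0.0, 1000.0),
        Reaction("R_dn1", {"X1": Fraction(-1), "T": Fraction(1)}, 0.0, 1000.0),
        Reaction("R_up2", {"A": Fraction(-1), "X2": Fraction(1)}, 0.0, 1000.0),
        Reaction("R_dn2", {"X2": Fraction(-1), "T": Fraction(1)}, 0.0, 1000.0),
    ]
    model = MetabolicModel(mets, rxns, None, {"EX_A": 10.0}, id="diamond")
    partition = define_core(model, ["EX_A"])
    return model, partition
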