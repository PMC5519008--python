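"""In-memory representation of a stoichiometric metabolic network.

The model is deliberately small: metabolites with elemental compositions,
reactions with exact-rational stoichiometric coefficients, flux bounds and
a medium.  Reversibility is encoded purely through bounds (``lb < 0``).
Exact rationals matter downstream: collapsing a subnetwork into a lumped
reaction relies on exact cancellation of intermediate metabolites.

Conversion to :class:`cobra.Model` is the bridge to the LP/MILP solver
layer; all optimization in lumpnet goes through cobrapy/optlang.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from fractions import Fraction

import cobra

from .errors import LookupError_

#: Cap on denominators when converting decimal coefficients to rationals.
COEFF_DENOMINATOR_CAP = 10 ** 6

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style chemical formula string into an element map.

    ``"C6H12O6" -> {"C": 6, "H": 12, "O": 6}``.  Repeated elements are
    summed.  Raises ``ValueError`` on anything that is not a plain
    element/count sequence (R-group formulas like ``"CHOR"`` parse, since
    ``R`` is treated as a pseudo-element, which mirrors common GEM usage).
    """
    if formula is None:
        raise ValueError("formula is None")
    pos = 0
    out: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparsable formula {formula!r}")
        pos = m.end()
        element, count = m.group(1), m.group(2)
        out[element] = out.get(element, 0) + (int(count) if count else 1)
    if pos != len(formula):
        raise ValueError(f"unparsable formula {formula!r}")
    return out


def format_formula(composition: dict[str, int]) -> str:
    """Inverse of :func:`parse_formula` (elements in alphabetical order)."""
    return "".join(
        f"{el}{n if n != 1 else ''}"
        for el, n in sorted(composition.items())
        if n != 0
    )


def as_fraction(x, cap: int = COEFF_DENOMINATOR_CAP) -> Fraction:
    """Convert a number to an exact rational, capping the denominator.

    Decimal coefficients from model files (e.g. ``0.1`` stored as a binary
    float) are snapped to the nearest rational with denominator <= cap.
    """
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(x).limit_denominator(cap)


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None  # None => missing, audits skip it
    charge: int | None = None

    @property
    def has_formula(self) -> bool:
        return self.formula is not None

    def atoms(self, element: str) -> int:
        if self.formula is None:
            return 0
        return self.formula.get(element, 0)

    @property
    def n_carbon(self) -> int:
        return self.atoms("C")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    name: str = ""

    def __post_init__(self):
        self.stoichiometry = {m: as_fraction(c) for m, c in self.stoichiometry.items()}
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_boundary(self) -> bool:
        """True for exchange/sink/demand reactions (single participant)."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, self.subsystem, self.name)


class MetabolicModel:
    """A stoichiometric network with bounds, formulas and a medium.

    Parameters
    ----------
    metabolites, reactions:
        Declared species and reactions.  Every stoichiometry key must
        reference a declared metabolite; metabolite ids must be unique.
    objective_reaction_id:
        Usually the biomass reaction; optional.
    medium:
        Map ``exchange reaction id -> max uptake flux`` (positive numbers,
        mmol/gDW/h).  Bounds remain authoritative; the medium records which
        exchanges feed the network and is used e.g. for the carbon cap.
    """

    def __init__(self, metabolites, reactions, objective_reaction_id=None,
                 medium=None, id="model"):
        self.id = id
        self.metabolites: list[Metabolite] = list(metabolites)
        self.reactions: list[Reaction] = list(reactions)
        self.objective_reaction_id = objective_reaction_id
        self.medium: dict[str, float] = dict(medium or {})
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise LookupError_(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise LookupError_(f"unknown reaction {rxn_id!r}") from None

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def species_of(self, rxn_ids) -> set[str]:
        out: set[str] = set()
        for rid in rxn_ids:
            out.update(self.reaction(rid).stoichiometry)
        return out

    @property
    def boundary_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_boundary]

    def drained_metabolites(self) -> set[str]:
        """Species with a boundary (exchange/sink/demand) reaction."""
        return {next(iter(r.stoichiometry)) for r in self.boundary_reactions}

    # -- mutation --------------------------------------------------------
    def add_reaction(self, reaction: Reaction) -> None:
        if reaction.id in self._rxn_index:
            raise ValueError(f"duplicate reaction id {reaction.id!r}")
        for met_id in reaction.stoichiometry:
            if met_id not in self._met_index:
                raise LookupError_(
                    f"reaction {reaction.id}: unknown metabolite {met_id!r}")
        self.reactions.append(reaction)
        self._rxn_index[reaction.id] = reaction

    def add_metabolite(self, metabolite: Metabolite) -> None:
        if metabolite.id in self._met_index:
            raise ValueError(f"duplicate metabolite id {metabolite.id!r}")
        self.metabolites.append(metabolite)
        self._met_index[metabolite.id] = metabolite

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            [Metabolite(m.id, m.name, m.compartment,
                        dict(m.formula) if m.formula is not None else None,
                        m.charge) for m in self.metabolites],
            [r.copy() for r in self.reactions],
            self.objective_reaction_id, dict(self.medium), self.id)

    def subnetwork_model(self, rxn_ids, id=None) -> "MetabolicModel":
        """New model restricted to the given reactions (and their species)."""
        rxn_ids = list(dict.fromkeys(rxn_ids))
        species = self.species_of(rxn_ids)
        mets = [m for m in self.metabolites if m.id in species]
        rxns = [self.reaction(rid).copy() for rid in rxn_ids]
        medium = {rid: up for rid, up in self.medium.items() if rid in set(rxn_ids)}
        obj = self.objective_reaction_id if self.objective_reaction_id in set(rxn_ids) else None
        return MetabolicModel(mets, rxns, obj, medium, id or f"{self.id}_sub")

    # -- checks ----------------------------------------------------------
    def validate(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise ValueError(f"duplicate reaction ids: {dupes}")
        declared = set(ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - declared
            if missing:
                raise ValueError(
                    f"reaction {r.id} references undeclared metabolites "
                    f"{sorted(missing)}")

    def elemental_imbalance(self, rxn_id: str) -> dict[str, Fraction]:
        """Per-element (and charge) residual of one reaction; exact."""
        rxn = self.reaction(rxn_id)
        residual: dict[str, Fraction] = {}
        for met_id, coeff in rxn.stoichiometry.items():
            met = self.metabolite(met_id)
            if met.formula is None:
                continue
            for el, n in met.formula.items():
                residual[el] = residual.get(el, Fraction(0)) + coeff * n
            if met.charge is not None:
                residual["charge"] = residual.get("charge", Fraction(0)) + coeff * met.charge
        return {el: v for el, v in residual.items() if v != 0}

    def __repr__(self):
        return (f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
                f"{len(self.reactions)} reactions>")


# -- cobra bridge --------------------------------------------------------

def to_cobra(model: MetabolicModel, rxn_ids=None) -> cobra.Model:
    """Build a :class:`cobra.Model` from (a reaction subset of) the model.

    The cobra model owns the optlang solver problem; every reaction comes
    with split non-negative forward/reverse variables, which downstream
    code uses directly for gating and L1 objectives.
    """
    cbm = cobra.Model(model.id)
    if rxn_ids is None:
        rxn_ids = model.reaction_ids
    rxn_ids = list(dict.fromkeys(rxn_ids))
    species = model.species_of(rxn_ids)
    cmets = {}
    for met_id in sorted(species):
        met = model.metabolite(met_id)
        cm = cobra.Metabolite(
            met.id, name=met.name or met.id, compartment=met.compartment or "c")
        if met.formula is not None:
            cm.formula = format_formula(met.formula)
        if met.charge is not None:
            cm.charge = met.charge
        cmets[met.id] = cm
    creactions = []
    for rid in rxn_ids:
        rxn = model.reaction(rid)
        cr = cobra.Reaction(rxn.id, name=rxn.name or rxn.id,
                            subsystem=rxn.subsystem)
        cr.add_metabolites({cmets[m]: float(c)
                            for m, c in rxn.stoichiometry.items()})
        cr.bounds = (rxn.lower_bound, rxn.upper_bound)
        creactions.append(cr)
    cbm.add_reactions(creactions)
    if model.objective_reaction_id and model.objective_reaction_id in set(rxn_ids):
        cbm.objective = model.objective_reaction_id
    return cbm


def from_cobra(cbm: cobra.Model) -> MetabolicModel:
    """Convert a cobrapy model into the exact-rational representation."""
    mets = []
    for cm in cbm.metabolites:
        formula = None
        if cm.formula:
            try:
                formula = parse_formula(cm.formula)
            except ValueError:
                formula = None
        charge = int(cm.charge) if cm.charge is not None and not (
            isinstance(cm.charge, float) and math.isnan(cm.charge)) else None
        mets.append(Metabolite(cm.id, cm.name or "", cm.compartment or "c",
                               formula, charge))
    rxns = []
    for cr in cbm.reactions:
        stoich = {m.id: as_fraction(c) for m, c in cr.metabolites.items()}
        rxns.append(Reaction(cr.id, stoich, float(cr.lower_bound),
                             float(cr.upper_bound), cr.subsystem or "",
                             cr.name or ""))
    objective_id = None
    for cr in cbm.reactions:
        if cr.objective_coefficient:
            objective_id = cr.id
            break
    try:
        medium = dict(cbm.medium)
    except Exception:
        medium = {}
    return MetabolicModel(mets, rxns, objective_id, medium, cbm.id or "model")
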