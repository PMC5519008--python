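"""Model I/O and biomass decomposition.

Reading and writing of SBML Level-3 FBC and BiGG-dialect JSON is delegated
to cobrapy; this module converts to/from the exact-rational in-memory
model and implements the biomass bookkeeping: splitting the biomass
reaction into individual building-block demands, the growth-associated
ATP maintenance (GAM) and the adenylate-pool imbalance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import cobra.io

from .errors import FormatError, LookupError_
from .model import MetabolicModel, Reaction, from_cobra, to_cobra

log = logging.getLogger(__name__)

#: Base species names (id without compartment suffix) of the GAM
#: hydrolysis pattern alpha * (ATP + H2O -> ADP + Pi + H).
GAM_PATTERN = {"atp": -1, "h2o": -1, "adp": 1, "pi": 1, "h": 1}


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".xml", ".sbml"}:
        return "sbml-fbc"
    if suffix == ".json":
        return "bigg-json"
    raise FormatError(f"cannot infer model format from {path.name!r}; "
                      "pass format='sbml-fbc' or 'bigg-json'")


def load_model(path, format: str | None = None) -> MetabolicModel:
    """Load a GEM from SBML-FBC or BiGG JSON into a :class:`MetabolicModel`.

    Metabolites without a parsable formula are loaded with an empty
    composition and flagged (``model.unaudited_metabolites``); elemental
    audits skip them.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"model file not found: {path}")
    fmt = _detect_format(path, format)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if fmt == "sbml-fbc":
                cbm = cobra.io.read_sbml_model(str(path))
            elif fmt == "bigg-json":
                cbm = cobra.io.load_json_model(str(path))
            else:
                raise FormatError(f"unknown format {fmt!r}")
    except FormatError:
        raise
    except Exception as exc:  # cobra raises various parse errors
        raise FormatError(f"cannot parse {path.name} as {fmt}: {exc}") from exc
    model = from_cobra(cbm)
    model.unaudited_metabolites = sorted(
        m.id for m in model.metabolites if m.formula is None)
    if model.unaudited_metabolites:
        log.warning("%d metabolites lack formulas and are excluded from "
                    "elemental audits (e.g. %s)",
                    len(model.unaudited_metabolites),
                    model.unaudited_metabolites[:3])
    return model


def write_model(model: MetabolicModel, path, format: str | None = None) -> None:
    """Write the model as SBML-FBC or BiGG JSON (chosen by extension)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    cbm = to_cobra(model)
    if fmt == "sbml-fbc":
        cobra.io.write_sbml_model(cbm, str(path))
    else:
        cobra.io.save_json_model(cbm, str(path))


# -- biomass decomposition ----------------------------------------------

@dataclass
class BiomassEntry:
    bbb_id: str
    n_j: Fraction  # mmol per gDW, > 0
    role: str  # "consumed" | "produced"


@dataclass
class BiomassComposition:
    """Lossless decomposition of a biomass reaction.

    ``entries`` are the individual building-block demands net of GAM;
    ``gam_atp`` is the matched ATP-hydrolysis stoichiometry
    alpha * (ATP + H2O -> ADP + Pi + H); ``adenylate_imbalance`` is the net
    ATP consumption not matched by ADP production (> 0 means the biomass
    demands de-novo synthesis of adenylate-pool metabolites).
    """

    biomass_id: str
    entries: list[BiomassEntry]
    gam_atp: Fraction
    adenylate_imbalance: Fraction
    gam_species: dict[str, str] = field(default_factory=dict)

    @property
    def consumed(self) -> list[BiomassEntry]:
        return [e for e in self.entries if e.role == "consumed"]

    @property
    def produced(self) -> list[BiomassEntry]:
        return [e for e in self.entries if e.role == "produced"]

    def demand(self, bbb_id: str) -> Fraction:
        for e in self.entries:
            if e.bbb_id == bbb_id:
                return e.n_j
        raise LookupError_(f"{bbb_id!r} is not a biomass entry")

    def reconstruct(self) -> dict[str, Fraction]:
        """Rebuild the biomass stoichiometry column, exactly."""
        stoich: dict[str, Fraction] = {}

        def add(met, val):
            if met is None or val == 0:
                return
            stoich[met] = stoich.get(met, Fraction(0)) + val

        for e in self.entries:
            add(e.bbb_id, -e.n_j if e.role == "consumed" else e.n_j)
        for base, sign in GAM_PATTERN.items():
            add(self.gam_species.get(base), sign * self.gam_atp)
        imb = self.adenylate_imbalance
        if imb > 0:
            add(self.gam_species.get("atp"), -imb)
        elif imb < 0:
            add(self.gam_species.get("adp"), -imb)
        return {m: c for m, c in stoich.items() if c != 0}


def _base_name(met_id: str, compartment: str) -> str:
    suffix = f"_{compartment}"
    return met_id[: -len(suffix)] if compartment and met_id.endswith(suffix) else met_id


def _find_gam_species(model: MetabolicModel, stoich) -> dict[str, str]:
    """Locate ATP/H2O/ADP/Pi/H among biomass participants (cytosolic first)."""
    found: dict[str, str] = {}
    for met_id in stoich:
        met = model.metabolite(met_id)
        base = _base_name(met_id, met.compartment).lower()
        if base in GAM_PATTERN and base not in found:
            found[base] = met_id
    return found


def parse_biomass(model: MetabolicModel, biomass_id: str | None = None,
                  gam_species: dict[str, str] | None = None) -> BiomassComposition:
    """Decompose the biomass reaction into building blocks, GAM and the
    adenylate-pool imbalance.

    GAM is the largest alpha such that alpha * (ATP + H2O -> ADP + Pi + H)
    is a sub-stoichiometry of the biomass reaction.  The ATP consumed (or
    ADP produced) beyond the matched hydrolysis goes to
    ``adenylate_imbalance``; every other coefficient, and any residual of
    the five pattern species, becomes an ordinary entry.  The decomposition
    is exact: :meth:`BiomassComposition.reconstruct` reproduces the biomass
    column of S.
    """
    biomass_id = biomass_id or model.objective_reaction_id
    if biomass_id is None:
        raise LookupError_("no biomass reaction id given and the model has "
                           "no objective reaction")
    rxn = model.reaction(biomass_id)
    stoich = dict(rxn.stoichiometry)
    species = gam_species or _find_gam_species(model, stoich)

    alpha = Fraction(0)
    if all(base in species for base in GAM_PATTERN):
        # matched amount available from each pattern species
        avail = [sign * stoich.get(species[base], Fraction(0))
                 for base, sign in GAM_PATTERN.items()]
        alpha = max(Fraction(0), min(avail))

    remainder = dict(stoich)
    for base, sign in GAM_PATTERN.items():
        if base in species:
            remainder[species[base]] = remainder.get(species[base], Fraction(0)) - sign * alpha

    imbalance = Fraction(0)
    atp_id, adp_id = species.get("atp"), species.get("adp")
    if atp_id is not None and adp_id is not None:
        atp_left = -remainder.get(atp_id, Fraction(0))   # still consumed
        adp_left = remainder.get(adp_id, Fraction(0))    # still produced
        imbalance = atp_left - adp_left
        if imbalance > 0:
            remainder[atp_id] = remainder.get(atp_id, Fraction(0)) + imbalance
        elif imbalance < 0:
            remainder[adp_id] = remainder.get(adp_id, Fraction(0)) + imbalance

    entries = []
    for met_id in stoich:  # preserve biomass reaction order
        coeff = remainder.get(met_id, Fraction(0))
        if coeff == 0:
            continue
        entries.append(BiomassEntry(met_id, abs(coeff),
                                    "consumed" if coeff < 0 else "produced"))
    comp = BiomassComposition(biomass_id, entries, alpha, imbalance, species)
    assert comp.reconstruct() == {m: c for m, c in stoich.items() if c != 0}, \
        "biomass decomposition is not lossless"
    return comp


# -- target sinks --------------------------------------------------------

def sink_id_for(met_id: str) -> str:
    return f"sink_{met_id}"


def add_target_sinks(model: MetabolicModel, targets) -> MetabolicModel:
    """Return a copy of the model with one irreversible drain per target.

    Each sink consumes its target with coefficient -1 and bounds [0, inf).
    Existing reaction ids are never touched; a clashing sink id gets a
    deterministic numeric suffix (logged).
    """
    out = model.copy()
    for met_id in targets:
        out.metabolite(met_id)  # raises LookupError_ for unknown targets
        sid = sink_id_for(met_id)
        if out.has_reaction(sid):
            k = 1
            while out.has_reaction(f"{sid}_{k}"):
                k += 1
            log.warning("sink id %s already taken, using %s_%d", sid, sid, k)
            sid = f"{sid}_{k}"
        out.add_reaction(Reaction(sid, {met_id: Fraction(-1)}, 0.0, float("inf"),
                                  subsystem="lumpnet-sink"))
    return out
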