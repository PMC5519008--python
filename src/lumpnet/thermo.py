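"""Thermodynamic directionality pre-processing.

Instead of embedding Gibbs-energy variables in the MILP, user-supplied
standard transformed Gibbs energies and metabolite concentration ranges
are turned into per-reaction directionality bounds before subnetwork
generation.  A direction is admitted iff some concentration vector within
the bounds makes it exergonic:

    dG'(c) = dG'0 + RT * sum_m n_m ln(c_m)

Forward is allowed iff min over the concentration box of dG'(c) minus the
uncertainty is < 0; reverse symmetrically.  Metabolites without
concentration bounds are held at 1 M (ln c = 0).  The returned bounds are
never wider than the model's own, so an empty data set leaves the
pipeline bit-identical to mass-balance-only mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ParameterError
from .model import MetabolicModel

#: Gas constant, kJ/mol/K.
R_KJ = 8.314462618e-3


@dataclass
class ThermoData:
    """Standard transformed Gibbs energies and concentration ranges.

    ``delta_g_prime_deg``: reaction id -> dG'0 (kJ/mol) at the stated
    temperature and ionic context; ``uncertainty``: reaction id -> kJ/mol;
    ``conc_bounds``: metabolite id -> (min, max) molar, both > 0.
    """

    delta_g_prime_deg: dict[str, float] = field(default_factory=dict)
    uncertainty: dict[str, float] = field(default_factory=dict)
    conc_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    temperature: float = 298.15  # K
    ionic_context: str = "default"

    def __post_init__(self):
        for met, (lo, hi) in self.conc_bounds.items():
            if not (0 < lo <= hi):
                raise ParameterError(
                    f"concentration bounds for {met!r} must satisfy "
                    f"0 < min <= max, got ({lo}, {hi})")

    @property
    def empty(self) -> bool:
        return not self.delta_g_prime_deg


def delta_g_range(model: MetabolicModel, rxn_id: str,
                  data: ThermoData) -> tuple[float, float]:
    """(min, max) of dG'(c) over the concentration box for one reaction."""
    dg0 = data.delta_g_prime_deg[rxn_id]
    rt = R_KJ * data.temperature
    lo = hi = dg0
    for met, coeff in model.reaction(rxn_id).stoichiometry.items():
        cmin, cmax = data.conc_bounds.get(met, (1.0, 1.0))
        n = float(coeff)
        terms = (n * math.log(cmin), n * math.log(cmax))
        lo += rt * min(terms)
        hi += rt * max(terms)
    return lo, hi


def directionality_bounds(model: MetabolicModel,
                          data: ThermoData) -> dict[str, tuple[float, float]]:
    """Per-reaction (lb, ub) tightened by thermodynamic feasibility.

    Only reactions covered by ``data`` appear in the result; uncovered
    reactions pass through unchanged.  Bounds are intersected with the
    model's original bounds (relaxation safety).
    """
    out: dict[str, tuple[float, float]] = {}
    for rid in data.delta_g_prime_deg:
        if not model.has_reaction(rid):
            continue
        rxn = model.reaction(rid)
        unc = data.uncertainty.get(rid, 0.0)
        lo, hi = delta_g_range(model, rid, data)
        forward_ok = (lo - unc) < 0
        reverse_ok = (hi + unc) > 0
        lb, ub = rxn.lower_bound, rxn.upper_bound
        if not forward_ok:
            ub = min(ub, 0.0)
        if not reverse_ok:
            lb = max(lb, 0.0)
        out[rid] = (lb, ub)
    return out


def apply_directionality(model: MetabolicModel,
                         bounds: dict[str, tuple[float, float]]) -> MetabolicModel:
    """Copy of the model with the tightened bounds applied."""
    out = model.copy()
    for rid, (lb, ub) in bounds.items():
        rxn = out.reaction(rid)
        rxn.lower_bound = max(rxn.lower_bound, lb)
        rxn.upper_bound = min(rxn.upper_bound, ub)
        if rxn.lower_bound > rxn.upper_bound:
            raise ParameterError(
                f"directionality bounds for {rid!r} are empty: "
                f"({rxn.lower_bound}, {rxn.upper_bound})")
    return out


def load_thermo_tsv(reactions_path, concentrations_path=None,
                    temperature: float = 298.15) -> ThermoData:
    """Read ThermoData from TSV files.

    ``reactions_path``: columns reaction_id, dG_prime_deg, uncertainty;
    ``concentrations_path``: columns metabolite_id, cmin, cmax.
    """
    dg, unc = {}, {}
    with open(reactions_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("reaction_id"):
                continue
            rid, dg0, u = line.split("\t")[:3]
            dg[rid] = float(dg0)
            unc[rid] = float(u)
    conc = {}
    if concentrations_path is not None:
        with open(concentrations_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.lower().startswith("metabolite_id"):
                    continue
                met, lo, hi = line.split("\t")[:3]
                conc[met] = (float(lo), float(hi))
    return ThermoData(dg, unc, conc, temperature)
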