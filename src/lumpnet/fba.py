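"""Thin flux-balance-analysis helpers over the cobra bridge."""

from __future__ import annotations

import math
from dataclasses import dataclass

from .model import MetabolicModel, to_cobra

FEASIBILITY_TOL = 1e-9


@dataclass
class FBAResult:
    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def fba(model: MetabolicModel, objective_rxn_id: str | None = None,
        rxn_ids=None, sense: str = "max", return_fluxes: bool = False) -> FBAResult:
    """LP-optimize one reaction flux subject to S.v = 0 and bounds."""
    objective_rxn_id = objective_rxn_id or model.objective_reaction_id
    if objective_rxn_id is None:
        raise ValueError("no objective reaction given")
    cbm = to_cobra(model, rxn_ids)
    cbm.objective = objective_rxn_id
    cbm.objective_direction = sense
    value = cbm.slim_optimize(error_value=float("nan"))
    status = cbm.solver.status
    fluxes = {}
    if return_fluxes and status == "optimal":
        fluxes = {r.id: r.flux for r in cbm.reactions}
    if math.isnan(value):
        value = 0.0
    return FBAResult(status, value, fluxes)


def mu_max(model: MetabolicModel, biomass_id: str | None = None) -> float:
    """Maximal specific growth rate (1/h) of the model at its medium."""
    res = fba(model, biomass_id or model.objective_reaction_id)
    return res.objective_value if res.ok else 0.0
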