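"""Linear-programming primitives: FBA, parsimonious FBA and FVA.

All three solve over the classical flux polytope
``{v : S v = 0, lb <= v <= ub}``. Backed by COBRApy/optlang (GLPK by
default); the backend is selectable through :data:`SOLVER`.

Tolerances follow standard LP practice: feasibility 1e-6, optimality 1e-9
relative. Unbounded FVA directions are clipped to the default bound
(±1000) so downstream arithmetic stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import cobra

from .model_core import MetabolicModel, _sbml_id, _un_sbml_id, to_cobra

__all__ = ["FBAResult", "FluxRange", "fba", "pfba", "fva", "LPConfigError"]

FEAS_TOL = 1e-6
SOLVER = "glpk"
CLIP_BOUND = 1000.0


class LPConfigError(ValueError):
    """Model is not set up for the requested LP (e.g. no objective)."""


@dataclass
class FBAResult:
    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class FluxRange:
    """Per-reaction (min, max) achievable flux intervals from FVA."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def __iter__(self):
        return iter(self.ranges)


def _prepare(model: MetabolicModel) -> cobra.Model:
    cm = to_cobra(model)
    cm.solver = SOLVER
    return cm


def _result_from(solution, model: MetabolicModel) -> FBAResult:
    fluxes = {rid: float(solution.fluxes[_sbml_id(rid)]) for rid in model.reactions}
    obj_rid = model.objective[0]
    return FBAResult(status="optimal", objective_value=fluxes[obj_rid], fluxes=fluxes)


def fba(model: MetabolicModel) -> FBAResult:
    """Maximize (or minimize) the model objective; one LP."""
    if model.objective is None:
        raise LPConfigError(f"model {model.id!r} has no objective set")
    cm = _prepare(model)
    solution = cm.optimize()
    if solution.status != "optimal":
        return FBAResult(status=solution.status, objective_value=float("nan"), fluxes={})
    return _result_from(solution, model)


def pfba(model: MetabolicModel, fixed_objective_fraction: float = 1.0) -> FBAResult:
    """Lexicographic parsimonious FBA.

    The objective flux is first fixed to ``fixed_objective_fraction`` of its
    optimum, then the total absolute flux sum is minimized (by splitting
    every reaction into non-negative forward/backward parts — exact for LP).
    The reported ``objective_value`` is the flux of the original objective
    reaction, not the flux sum.
    """
    if model.objective is None:
        raise LPConfigError(f"model {model.id!r} has no objective set")
    if not (0.0 < fixed_objective_fraction <= 1.0):
        raise ValueError("fixed_objective_fraction must be in (0, 1]")
    cm = _prepare(model)
    try:
        solution = cobra.flux_analysis.pfba(
            cm, fraction_of_optimum=fixed_objective_fraction)
    except cobra.exceptions.Infeasible:
        base = cm.slim_optimize(error_value=float("nan"))
        return FBAResult(
            status="infeasible",
            objective_value=base * fixed_objective_fraction,
            fluxes={})
    return _result_from(solution, model)


def fva(model: MetabolicModel, reaction_ids, objective_floor: float | None = None,
        ) -> FluxRange:
    """Min/max achievable flux per listed reaction (2 LPs each).

    ``objective_floor`` (optional) constrains the objective reaction's flux
    to at least that value (at most, for a minimization objective) while the
    ranges are computed.
    """
    reaction_ids = list(reaction_ids)
    missing = [r for r in reaction_ids if r not in model.reactions]
    if missing:
        raise KeyError(f"reactions not in model: {missing}")
    cm = _prepare(model)
    if objective_floor is not None:
        if model.objective is None:
            raise LPConfigError("objective_floor given but model has no objective")
        obj = cm.reactions.get_by_id(_sbml_id(model.objective[0]))
        if model.objective[1] == "max":
            obj.lower_bound = max(obj.lower_bound, objective_floor)
        else:
            obj.upper_bound = min(obj.upper_bound, objective_floor)
    if math.isnan(cm.slim_optimize(error_value=float("nan"))):
        raise LPConfigError(
            f"model {model.id!r} infeasible under objective_floor={objective_floor}")
    ranges: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        rxn = cm.reactions.get_by_id(_sbml_id(rid))
        lo, hi = [], []
        for sense, acc in (("min", lo), ("max", hi)):
            cm.objective = rxn
            cm.objective_direction = sense
            val = cm.slim_optimize(error_value=float("nan"))
            if math.isnan(val) or math.isinf(val):
                val = -CLIP_BOUND if sense == "min" else CLIP_BOUND
            acc.append(float(val))
        vmin = max(min(lo[0], hi[0]), -CLIP_BOUND)
        vmax = min(max(lo[0], hi[0]), CLIP_BOUND)
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges=ranges)
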