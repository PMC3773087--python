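"""Deterministic linear-programming core: FBA and flux-range (FVA) queries.

Flux balance analysis solves

    max/min  v_obj
    s.t.     S v = 0,   lb <= v <= ub,   v_r = c_r  for each fixed reaction r

over the stoichiometric matrix S.  Flux variability analysis asks, for one
target reaction under the same constraint set, for the minimum and maximum
achievable flux; applied to every reaction it characterises the space of
alternate optima.

The backend is HiGHS via :func:`scipy.optimize.linprog` with a fixed
(dual-simplex) method and tight feasibility tolerances, so repeated runs
agree bitwise on objective values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .core import FluxRange, FluxVector, MetabolicModel, stoichiometric_matrix

#: solver tolerances: feasibility/optimality two orders tighter than the
#: 1e-3 resolution of 3-decimal report tables
FEASIBILITY_TOL = 1e-9
#: classification tolerance for calling a flux range zero/constant, mmol/gDW/h
CLASSIFY_TOL = 1e-6

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": FEASIBILITY_TOL,
    "dual_feasibility_tolerance": FEASIBILITY_TOL,
}


class InfeasibleError(RuntimeError):
    """Raised by range queries when the constraint set is infeasible."""

    def __init__(self, message: str, status: str = "infeasible"):
        super().__init__(message)
        self.status = status


@dataclass
class LPOutcome:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: FluxVector | None


def _effective_bounds(
    model: MetabolicModel, fixed: Mapping[str, float] | None
) -> list[tuple[float, float]] | None:
    """Bounds with equality fixings applied; None if a fixing falls outside
    the model bounds (empty feasible set)."""
    fixed = fixed or {}
    for rid in fixed:
        model.reaction(rid)  # raises KeyError for unknown ids
    bounds = []
    for rxn in model.reactions:
        if rxn.id in fixed:
            value = float(fixed[rxn.id])
            if (
                value < rxn.lower_bound - FEASIBILITY_TOL
                or value > rxn.upper_bound + FEASIBILITY_TOL
            ):
                return None
            bounds.append((value, value))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    return bounds


def _solve(
    S: np.ndarray,
    c: np.ndarray,
    bounds: list[tuple[float, float]],
):
    return linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs-ds",
        options=_HIGHS_OPTIONS,
    )


def solve_fba(
    model: MetabolicModel,
    objective_id: str,
    sense: str = "maximize",
    fixed: Mapping[str, float] | None = None,
) -> LPOutcome:
    """Solve one FBA problem.

    ``fixed`` imposes equality constraints v_r = value (e.g. the donor uptake
    or a growth-rate fix).  Infeasible fixings yield ``status="infeasible"``,
    not an exception; unknown reaction ids raise ``KeyError``.
    """
    if sense not in ("maximize", "minimize"):
        raise ValueError(f"sense must be maximize or minimize, got {sense!r}")
    j = model._rxn_index[model.reaction(objective_id).id]
    S = stoichiometric_matrix(model)
    n = S.shape[1]
    c = np.zeros(n)
    c[j] = -1.0 if sense == "maximize" else 1.0
    bounds = _effective_bounds(model, fixed)
    if bounds is None:
        return LPOutcome("infeasible", None, None)
    res = _solve(S, c, bounds)
    if res.status == 2:
        return LPOutcome("infeasible", None, None)
    if res.status == 3:
        return LPOutcome("unbounded", None, None)
    if res.status != 0:
        raise RuntimeError(f"LP solver failure: {res.message}")
    objective = float(res.x[j])
    fluxes = FluxVector(
        values={rxn.id: float(v) for rxn, v in zip(model.reactions, res.x)},
        objective_id=objective_id,
        objective_value=objective,
    )
    return LPOutcome("optimal", objective, fluxes)


def flux_range(
    model: MetabolicModel,
    target_id: str,
    fixed: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """(min, max) achievable flux through ``target_id`` under S v = 0, the
    model bounds, and the equality fixings."""
    lo = solve_fba(model, target_id, "minimize", fixed)
    if lo.status != "optimal":
        raise InfeasibleError(
            f"flux_range({target_id}): minimisation {lo.status}", lo.status
        )
    hi = solve_fba(model, target_id, "maximize", fixed)
    if hi.status != "optimal":
        raise InfeasibleError(
            f"flux_range({target_id}): maximisation {hi.status}", hi.status
        )
    vmin, vmax = lo.objective_value, hi.objective_value
    if vmin > vmax:  # numerically-equal optima can land a hair out of order
        vmin, vmax = vmax, vmin
    return (vmin, vmax)


def fva_all(
    model: MetabolicModel, fixed: Mapping[str, float] | None = None
) -> FluxRange:
    """Flux variability analysis over every reaction: 2n LP solves."""
    return FluxRange(
        {rxn.id: flux_range(model, rxn.id, fixed) for rxn in model.reactions}
    )


def classify_reactions(
    ranges: FluxRange, tol: float = CLASSIFY_TOL
) -> dict[str, str]:
    """Classify each reaction's FVA range.

    non_functional: the range is [0, 0] (within tol) — the reaction carries
    no flux under the given constraints; constant: a single nonzero value;
    variable: genuine slack.
    """
    out: dict[str, str] = {}
    for rid, (vmin, vmax) in ranges.items():
        if abs(vmin) <= tol and abs(vmax) <= tol:
            out[rid] = "non_functional"
        elif abs(vmax - vmin) <= tol:
            out[rid] = "constant"
        else:
            out[rid] = "variable"
    return out


def magnitude_range(signed: tuple[float, float]) -> tuple[float, float]:
    """Convert a signed flux range into a |flux| range.

    Exchange fluxes are negative for uptake; the respiration rate is reported
    as the magnitude of the terminal-acceptor exchange flux.
    """
    lo, hi = signed
    if lo <= 0.0 <= hi:
        return (0.0, max(-lo, hi))
    return (min(abs(lo), abs(hi)), max(abs(lo), abs(hi)))
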