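"""Optimal/suboptimal-growth respiration experiments.

Growth is fixed at a fraction k of the FBA growth optimum (v_gr = k *
v_gr_max, donor uptake held constant) and the achievable range of the
respiration rate — the flux magnitude through the terminal-acceptor
exchange — is computed by FVA for every k on a grid.  Because the LP value
function is concave in the growth fix, the maximum-respiration column is
non-increasing and the minimum-respiration column non-decreasing in v_gr:
the competitive trade-off between biosynthesis and respiration.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import FluxVector, MetabolicModel
from .lp import InfeasibleError, flux_range, magnitude_range, solve_fba


@dataclass
class SweepConfig:
    """Study conditions for a sweep: donor uptake magnitude (mmol/gDW/h) and
    the grid of growth fractions k in [0, 1]."""

    uptake_rate: float = 13.630
    k_grid: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.uptake_rate <= 0:
            raise ValueError("uptake_rate must be positive")
        ks = list(self.k_grid)
        if any(k < 0 or k > 1 for k in ks) or ks != sorted(set(ks)):
            raise ValueError("k_grid must be strictly increasing within [0, 1]")

    def uptake_fix(self, model: MetabolicModel) -> dict[str, float]:
        # uptake of magnitude u = exchange flux fixed at -u
        return {model.uptake_exchange_id: -self.uptake_rate}


def optimal_growth(model: MetabolicModel, config: SweepConfig | None = None) -> float:
    """Maximum growth rate (h^-1) at the fixed donor uptake."""
    config = config or SweepConfig()
    outcome = solve_fba(
        model, model.biomass_id, "maximize", config.uptake_fix(model)
    )
    if outcome.status != "optimal":
        raise InfeasibleError(
            f"optimal growth: FBA {outcome.status} at uptake {config.uptake_rate}",
            outcome.status,
        )
    return outcome.objective_value


def respiration_range(
    model: MetabolicModel, growth_rate: float, config: SweepConfig | None = None
) -> tuple[float, float]:
    """(min, max) respiration magnitude at one fixed growth rate."""
    config = config or SweepConfig()
    fixed = config.uptake_fix(model)
    fixed[model.biomass_id] = growth_rate
    signed = flux_range(model, model.respiration_exchange_id, fixed)
    return magnitude_range(signed)


def respiration_table(
    model: MetabolicModel, config: SweepConfig | None = None
) -> pd.DataFrame:
    """One row per k on the grid: (v_gr, v_res_min, v_res_max), ordered by
    descending growth rate."""
    config = config or SweepConfig()
    v_gr_max = optimal_growth(model, config)
    rows = []
    for k in config.k_grid:
        v_gr = k * v_gr_max
        v_min, v_max = respiration_range(model, v_gr, config)
        rows.append({"v_gr": v_gr, "v_res_min": v_min, "v_res_max": v_max})
    return (
        pd.DataFrame(rows, columns=["v_gr", "v_res_min", "v_res_max"])
        .sort_values("v_gr", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def respiration_extreme_vectors(
    model: MetabolicModel, growth_rate: float, config: SweepConfig | None = None
) -> tuple[FluxVector, FluxVector]:
    """Flux vectors at maximum and minimum respiration magnitude for one
    fixed growth rate.

    Alternate optima exist; these are single deterministic LP solutions, and
    only objective values / FVA ranges are contractual.
    """
    config = config or SweepConfig()
    fixed = config.uptake_fix(model)
    fixed[model.biomass_id] = growth_rate
    lo = solve_fba(model, model.respiration_exchange_id, "minimize", fixed)
    hi = solve_fba(model, model.respiration_exchange_id, "maximize", fixed)
    for outcome in (lo, hi):
        if outcome.status != "optimal":
            raise InfeasibleError(
                f"respiration extremes: FBA {outcome.status}", outcome.status
            )
    vmin, vmax = lo.objective_value, hi.objective_value
    if vmin <= 0.0 <= vmax:
        # signed range spans zero: the minimum-magnitude state is flux = 0
        zero = dict(fixed)
        zero[model.respiration_exchange_id] = 0.0
        at_zero = solve_fba(model, model.biomass_id, "maximize", zero)
        min_vec = at_zero.fluxes
        max_vec = (lo if -vmin >= vmax else hi).fluxes
    elif vmax < 0.0:  # pure uptake of the acceptor (the usual convention)
        max_vec, min_vec = lo.fluxes, hi.fluxes
    else:
        max_vec, min_vec = hi.fluxes, lo.fluxes
    return max_vec, min_vec


def variance_report(
    model: MetabolicModel,
    growth_rate: float,
    config: SweepConfig | None = None,
    threshold: float = 0.01,
) -> pd.DataFrame:
    """Reactions whose flux differs between the maximum- and minimum-
    respiration states by more than ``threshold`` relative to the larger
    flux magnitude (reference max(|f_max|, |f_min|, 1e-6), a symmetric
    relative-difference filter), grouped by subsystem."""
    max_vec, min_vec = respiration_extreme_vectors(model, growth_rate, config)
    rows = []
    for rxn in model.reactions:
        f_max = max_vec.values[rxn.id]
        f_min = min_vec.values[rxn.id]
        reference = max(abs(f_max), abs(f_min), 1e-6)
        if abs(f_max - f_min) > threshold * reference:
            rows.append(
                {
                    "reaction": rxn.id,
                    "flux_at_max_res": f_max,
                    "flux_at_min_res": f_min,
                    "subsystem": rxn.subsystem,
                }
            )
    return (
        pd.DataFrame(
            rows, columns=["reaction", "flux_at_max_res", "flux_at_min_res", "subsystem"]
        )
        .sort_values(["subsystem", "reaction"], kind="stable")
        .reset_index(drop=True)
    )


def reducing_equivalent_report(
    model: MetabolicModel,
    growth_rate: float,
    config: SweepConfig | None = None,
    re_reaction_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Fluxes through named reducing-equivalent-producing reactions under
    maximum vs minimum respiration, plus their difference."""
    re_reaction_ids = re_reaction_ids or []
    for rid in re_reaction_ids:
        model.reaction(rid)  # KeyError on unknown ids
    if not re_reaction_ids:
        return pd.DataFrame(
            columns=["reaction", "flux_at_max_res", "flux_at_min_res", "difference"]
        )
    max_vec, min_vec = respiration_extreme_vectors(model, growth_rate, config)
    rows = [
        {
            "reaction": rid,
            "flux_at_max_res": max_vec.values[rid],
            "flux_at_min_res": min_vec.values[rid],
            "difference": max_vec.values[rid] - min_vec.values[rid],
        }
        for rid in re_reaction_ids
    ]
    return pd.DataFrame(rows)
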