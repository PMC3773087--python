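"""Iterative-FVA strain design.

At a fixed suboptimal growth rate and donor uptake, the wild network can
realise a whole interval of respiration rates: the slack is electron leakage
through secreted byproducts.  The designer closes that interval greedily:

1. FVA on the respiration magnitude; stop when max - min <= tol.
2. Take one minimum-respiration flux solution.
3. Rank secreted byproducts by electron-weighted secretion flux
   (degree of reduction x secretion rate), ties lexicographic.
4. Knock out every secretion transporter of the top-ranked metabolite.
5. Record the post-knockout respiration range and repeat.

Each step can only shrink the feasible flux set, so the minimum-respiration
column is non-decreasing and the maximum column non-increasing along the
trajectory; on convergence the variant respires at its maximum whenever it
grows at the design rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MetabolicModel, knockout
from .electrons import secretion_electron_ranking
from .lp import InfeasibleError, flux_range
from .sweep import (
    SweepConfig,
    optimal_growth,
    respiration_extreme_vectors,
    respiration_range,
    respiration_table,
)

#: convergence tolerance on the respiration gap, mmol/gDW/h (reports print
#: 3 decimals; this is an order of magnitude tighter)
DESIGN_TOL = 1e-4


@dataclass
class KnockoutStep:
    reaction_ids: tuple[str, ...]
    culprit_metabolite: str
    v_res_min: float
    v_res_max: float


@dataclass
class KnockoutTrajectory:
    steps: list[KnockoutStep]
    final_model: MetabolicModel
    converged: bool
    design_growth_rate: float
    diagnostic: str = ""


def _secretion_transporters(model: MetabolicModel, met_id: str) -> list[str]:
    """Non-exchange reactions that touch the given extracellular metabolite
    and still carry nonzero bounds — the transport step(s) feeding its
    secretion."""
    return sorted(
        rxn.id
        for rxn in model.reactions
        if rxn.kind != "exchange"
        and met_id in rxn.stoichiometry
        and not (rxn.lower_bound == 0.0 and rxn.upper_bound == 0.0)
    )


def design_variant(
    model: MetabolicModel,
    growth_rate: float,
    config: SweepConfig | None = None,
    tol: float = DESIGN_TOL,
    max_iter: int = 50,
) -> KnockoutTrajectory:
    """Design a variant achieving min respiration = max respiration at the
    given growth rate by iteratively deleting electron-leaking secretion
    transporters.  Returns the full trajectory whether or not converged."""
    config = config or SweepConfig()
    current = model.copy()
    steps: list[KnockoutStep] = []

    v_min, v_max = respiration_range(current, growth_rate, config)
    for _ in range(max_iter):
        if v_max - v_min <= tol:
            return KnockoutTrajectory(steps, current, True, growth_rate)
        _, min_vec = respiration_extreme_vectors(current, growth_rate, config)
        ranking = secretion_electron_ranking(current, min_vec)
        if not ranking:
            return KnockoutTrajectory(
                steps, current, False, growth_rate,
                diagnostic=(
                    f"respiration gap {v_max - v_min:.6g} not attributable to "
                    "secreted byproducts"
                ),
            )
        culprit = ranking[0][0]
        transporters = _secretion_transporters(current, culprit)
        if not transporters:
            return KnockoutTrajectory(
                steps, current, False, growth_rate,
                diagnostic=f"no active transporter found for {culprit}",
            )
        current = knockout(current, transporters)
        v_min, v_max = respiration_range(current, growth_rate, config)
        steps.append(KnockoutStep(tuple(transporters), culprit, v_min, v_max))
    return KnockoutTrajectory(
        steps, current, v_max - v_min <= tol, growth_rate,
        diagnostic="iteration limit reached",
    )


def trajectory_table(trajectory: KnockoutTrajectory) -> pd.DataFrame:
    """One row per knockout step with the cumulative knockout label and the
    respiration range after the deletion."""
    rows = []
    cumulative: list[str] = []
    for step in trajectory.steps:
        cumulative.extend(step.reaction_ids)
        rows.append(
            {
                "knockouts": " + ".join(cumulative),
                "culprit": step.culprit_metabolite,
                "v_res_min": step.v_res_min,
                "v_res_max": step.v_res_max,
            }
        )
    return pd.DataFrame(rows, columns=["knockouts", "culprit", "v_res_min", "v_res_max"])


def atp_range_table(
    model: MetabolicModel,
    config: SweepConfig | None = None,
    atp_reaction_id: str | None = None,
) -> pd.DataFrame:
    """Flux range through the ATP-synthesis reaction for each growth
    fraction on the grid (the energy-synthesis analogue of the respiration
    sweep)."""
    if atp_reaction_id is None:
        raise ValueError("configuration error: no ATP-synthesis reaction id given")
    config = config or SweepConfig()
    model.reaction(atp_reaction_id)  # KeyError on unknown id
    v_gr_max = optimal_growth(model, config)
    rows = []
    for k in config.k_grid:
        fixed = config.uptake_fix(model)
        fixed[model.biomass_id] = k * v_gr_max
        v_min, v_max = flux_range(model, atp_reaction_id, fixed)
        rows.append({"v_gr": k * v_gr_max, "v_atp_min": v_min, "v_atp_max": v_max})
    return (
        pd.DataFrame(rows, columns=["v_gr", "v_atp_min", "v_atp_max"])
        .sort_values("v_gr", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def validate_variant(
    variant: MetabolicModel,
    config: SweepConfig | None = None,
    tol: float = DESIGN_TOL,
) -> pd.DataFrame:
    """Respiration sweep over the variant with a flag wherever a residual
    respiration gap larger than tol survives."""
    table = respiration_table(variant, config)
    table["flagged"] = (table["v_res_max"] - table["v_res_min"]) > tol
    return table
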