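"""Degree-of-reduction electron bookkeeping.

The degree of reduction gamma of a species is the number of electrons
released on its complete oxidation to the reference states CO2, H2O, NH3,
phosphate and sulfate:

    gamma = 4 C + 1 H - 2 O - 3 N + 5 P + 6 S - charge

Acetate (C2H3O2, -1) carries 8 electrons, formate (CHO2, -1) carries 2, the
references carry 0.  Electron-carrier pseudo-metabolites (NADH, quinol,
reduced ferredoxin/cytochrome, the reduced acceptor) declare gamma directly
on the metabolite.

On an electron-balanced model every internal reaction conserves gamma, so
for any steady-state flux vector

    gamma_donor * uptake = v_res * gamma_acceptor_step + electrons secreted
                           + electrons fixed in biomass,

which is what lets the gap between maximum and minimum respiration at one
growth rate be decomposed exactly into electron-weighted secretion
differences — the quantitative form of "byproduct secretion loses current".
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .core import FluxVector, MetabolicModel, Metabolite, Reaction

#: electrons contributed per atom relative to the reference states
GAMMA_PER_ELEMENT = {"C": 4, "H": 1, "O": -2, "N": -3, "P": 5, "S": 6}


def degree_of_reduction(formula: Mapping[str, int], charge: int = 0) -> float:
    """Electrons per molecule available on full oxidation."""
    unknown = sorted(set(formula) - set(GAMMA_PER_ELEMENT))
    if unknown:
        raise ValueError(f"unknown elements in formula: {unknown}")
    gamma = sum(GAMMA_PER_ELEMENT[e] * n for e, n in formula.items())
    return float(gamma - charge)


def metabolite_gamma(met: Metabolite) -> float | None:
    """Degree of reduction of a metabolite: the declared value if present,
    else derived from formula and charge; None if unscorable."""
    if met.gamma is not None:
        return float(met.gamma)
    if met.formula is None:
        return None
    return degree_of_reduction(met.formula, met.charge or 0)


def electron_balance(reaction: Reaction, model: MetabolicModel) -> float | None:
    """Net electron change of a reaction: sum of coefficient x gamma.

    Zero for a balanced internal reaction; for a single-metabolite exchange
    it equals the gamma of the exchanged species (so uptake flux x balance
    counts electrons entering the system).  Returns None ("unscored") when
    any participating metabolite has neither formula nor declared gamma.
    """
    total = 0.0
    for mid, coeff in reaction.stoichiometry.items():
        gamma = metabolite_gamma(model.metabolite(mid))
        if gamma is None:
            return None
        total += coeff * gamma
    return total


def biomass_electron_content(model: MetabolicModel) -> float:
    """Electrons fixed per unit biomass flux: gamma-weighted sum of the
    precursors the biomass reaction consumes (products, e.g. ADP/Pi
    regenerated from the ATP cost, are netted out)."""
    biomass = model.reaction(model.biomass_id)
    total = 0.0
    for mid, coeff in biomass.stoichiometry.items():
        gamma = metabolite_gamma(model.metabolite(mid))
        if gamma is None:
            continue  # energy-currency pseudo-metabolites without gamma
        total -= coeff * gamma  # consumed (coeff < 0) counts positive
    return total


def _acceptor_metabolite_ids(model: MetabolicModel) -> set[str]:
    """The terminal acceptor and its immediate reduction products: the
    acceptor-exchange metabolite plus every metabolite of the non-exchange
    reactions it participates in (e.g. Fe3+ reductase, hence Fe2+)."""
    resp = model.reaction(model.respiration_exchange_id)
    (acceptor,) = resp.stoichiometry
    linked = {acceptor}
    for rxn in model.reactions:
        if rxn.kind != "exchange" and acceptor in rxn.stoichiometry:
            linked.update(rxn.stoichiometry)
    return linked


def secretion_electron_ranking(
    model: MetabolicModel, flux_vector: FluxVector
) -> list[tuple[str, float]]:
    """Secreted byproducts ranked by electron-weighted secretion flux,
    descending; ties broken lexicographically by metabolite id.

    Excluded: species with gamma 0 or unscored (CO2, water, protons), the
    respiration acceptor and its reduction product, and anything being taken
    up rather than secreted.
    """
    excluded = _acceptor_metabolite_ids(model)
    rows: list[tuple[str, float]] = []
    for rxn in model.exchanges():
        (mid,) = rxn.stoichiometry
        if mid in excluded:
            continue
        # exchange stoichiometry is {met: -1}; positive flux = secretion,
        # so the secretion rate of the metabolite is -coeff * flux
        coeff = rxn.stoichiometry[mid]
        flux = -coeff * flux_vector.values.get(rxn.id, 0.0)
        if flux <= 1e-9:
            continue
        gamma = metabolite_gamma(model.metabolite(mid))
        if gamma is None or gamma == 0.0:
            continue
        rows.append((mid, gamma * flux))
    rows.sort(key=lambda item: (-item[1], item[0]))
    return rows


def respiration_gap_decomposition(
    model: MetabolicModel,
    flux_at_max_res: FluxVector,
    flux_at_min_res: FluxVector,
) -> pd.DataFrame:
    """Attribute the respiration gap between two flux states to
    electron-weighted secretion differences.

    One row per exchanged byproduct with columns ``metabolite``,
    ``delta_secretion`` (secretion at min-respiration minus at
    max-respiration), ``gamma`` and ``electron_contribution``.  Unscored
    exchanges are collected into a trailing ``<unscored>`` residual row.  On
    a fully scored electron-balanced model the contribution column sums to
    v_res_max - v_res_min.
    """
    excluded = _acceptor_metabolite_ids(model)
    rows = []
    unscored = []
    for rxn in model.exchanges():
        (mid,) = rxn.stoichiometry
        if mid in excluded:
            continue
        coeff = rxn.stoichiometry[mid]
        delta = (
            flux_at_min_res.values.get(rxn.id, 0.0)
            - flux_at_max_res.values.get(rxn.id, 0.0)
        ) * -coeff  # secretion difference, positive = more secreted at min-res
        gamma = metabolite_gamma(model.metabolite(mid))
        if gamma is None:
            if abs(delta) > 1e-9:
                unscored.append(mid)
            continue
        if abs(delta * gamma) <= 1e-9:
            continue
        rows.append(
            {
                "metabolite": mid,
                "delta_secretion": delta,
                "gamma": gamma,
                "electron_contribution": gamma * delta,
            }
        )
    rows.sort(key=lambda r: (-r["electron_contribution"], r["metabolite"]))
    if unscored:
        rows.append(
            {
                "metabolite": "<unscored>",
                "delta_secretion": float("nan"),
                "gamma": float("nan"),
                "electron_contribution": float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["metabolite", "delta_secretion", "gamma", "electron_contribution"],
    )


def reducing_equivalent_producers(model: MetabolicModel) -> list[str]:
    """Internal reactions with net production of electron-carrier
    pseudo-metabolites (declared-gamma species such as NADH, quinol, reduced
    ferredoxin) — the catabolic steps that load the electron transport
    chain."""
    biomass_draws = {
        mid
        for mid, coeff in model.reaction(model.biomass_id).stoichiometry.items()
        if coeff < 0
    }

    def is_carrier(mid: str) -> bool:
        met = model.metabolite(mid)
        # carriers are formula-less declared-gamma species; biomass
        # precursors (e.g. an acetyl-CoA lump) are building blocks, not
        # carriers, even when their gamma is declared
        return (
            met.gamma is not None
            and met.gamma > 0
            and met.formula is None
            and mid not in biomass_draws
        )

    out = []
    for rxn in model.reactions:
        if rxn.kind == "exchange" or rxn.id == model.biomass_id:
            continue
        net = sum(
            coeff * model.metabolite(mid).gamma
            for mid, coeff in rxn.stoichiometry.items()
            if is_carrier(mid)
        )
        if net > 1e-9:
            out.append(rxn.id)
    return sorted(out)


def electron_ledger(model: MetabolicModel, flux_vector: FluxVector) -> pd.DataFrame:
    """Per-exchange electron-weighted fluxes (e- mmol/gDW/h) for one flux
    state, positive = electrons leaving the system as secreted species."""
    rows = []
    for rxn in model.exchanges():
        (mid,) = rxn.stoichiometry
        gamma = metabolite_gamma(model.metabolite(mid))
        flux = -rxn.stoichiometry[mid] * flux_vector.values.get(rxn.id, 0.0)
        rows.append(
            {
                "exchange": rxn.id,
                "metabolite": mid,
                "flux": flux,
                "gamma": gamma if gamma is not None else float("nan"),
                "electron_flux": flux * gamma if gamma is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows).sort_values("exchange").reset_index(drop=True)
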