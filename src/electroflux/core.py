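"""Domain types for stoichiometric metabolic models and flux results.

A :class:`MetabolicModel` is a plain in-memory container: metabolites,
reactions, and three designated *role* reactions — the biomass
pseudo-reaction (whose flux is the growth rate, h^-1), the electron-donor
exchange (e.g. acetate) and the terminal-acceptor exchange (e.g. Fe(III)),
whose flux magnitude is the respiration rate.  All other fluxes are in
mmol/gDW/h.

Sign convention for exchange reactions: positive flux = secretion,
negative = uptake.  Fixing donor uptake at magnitude ``u`` therefore means
constraining the donor exchange flux to ``-u``.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

COMPARTMENTS = ("cytoplasm", "extracellular")

REACTION_KINDS = ("metabolic", "transport", "exchange")


class StructuralError(ValueError):
    """A model violates a structural invariant (unresolved id, empty stoichiometry...)."""


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` maps element symbol to count (e.g. acetate ``{"C": 2, "H": 3,
    "O": 2}`` with ``charge=-1``).  ``gamma`` optionally declares the degree
    of reduction directly; it is how electron-carrier pseudo-metabolites
    (NADH, quinol, reduced cytochrome/ferredoxin, reduced acceptor) enter the
    electron ledger when they have no meaningful elemental formula.
    """

    id: str
    name: str = ""
    compartment: str = "cytoplasm"
    formula: dict[str, int] | None = None
    charge: int | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise StructuralError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  Exchange reactions touch
    exactly one extracellular metabolite.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    kind: str = "metabolic"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise StructuralError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise StructuralError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if self.kind not in REACTION_KINDS:
            raise StructuralError(
                f"reaction {self.id!r}: kind {self.kind!r} not in {REACTION_KINDS}"
            )


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    uptake_exchange_id: str
    respiration_exchange_id: str
    id: str = "model"
    _met_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)
    _rxn_index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._met_index = {}
        for i, met in enumerate(self.metabolites):
            if met.id in self._met_index:
                raise StructuralError(f"duplicate metabolite id {met.id!r}")
            self._met_index[met.id] = i
        self._rxn_index = {}
        for j, rxn in enumerate(self.reactions):
            if rxn.id in self._rxn_index:
                raise StructuralError(f"duplicate reaction id {rxn.id!r}")
            self._rxn_index[rxn.id] = j

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self._met_index[met_id]]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self._rxn_index[rxn_id]]
        except KeyError:
            raise KeyError(f"unknown reaction id {rxn_id!r}") from None

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)


@dataclass
class FluxVector:
    """One steady-state flux assignment over all reactions of a model."""

    values: dict[str, float]
    objective_id: str
    objective_value: float

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]


@dataclass
class FluxRange:
    """Per-reaction achievable [min, max] flux — the FVA result."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rxn_id: str) -> tuple[float, float]:
        return self.ranges[rxn_id]

    def __iter__(self):
        return iter(self.ranges)

    def __len__(self) -> int:
        return len(self.ranges)

    def items(self):
        return self.ranges.items()


# ---------------------------------------------------------------------------
# operations


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Dense m-metabolites x n-reactions matrix S with S[i, j] the coefficient
    of metabolite i in reaction j."""
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in model._met_index:
                raise StructuralError(
                    f"reaction {rxn.id!r}: unresolved metabolite id {met_id!r}"
                )
            S[model._met_index[met_id], j] = coeff
    return S


def _reaction_fully_scored(model: MetabolicModel, rxn: Reaction) -> bool:
    return all(
        model.metabolite(mid).formula is not None
        and model.metabolite(mid).charge is not None
        for mid in rxn.stoichiometry
        if mid in model._met_index
    )


def validate_model(model: MetabolicModel) -> list[str]:
    """Structural validation.  Returns a list of human-readable violations;
    an empty list means the model is valid.

    Element/charge balance is checked only for non-exchange, non-biomass
    reactions whose metabolites all carry full formula and charge data; the
    biomass pseudo-reaction is a sink by construction and exchange reactions
    cross the system boundary.
    """
    report: list[str] = []

    for role, rid in (
        ("biomass", model.biomass_id),
        ("uptake exchange", model.uptake_exchange_id),
        ("respiration exchange", model.respiration_exchange_id),
    ):
        if rid not in model._rxn_index:
            report.append(f"role {role}: reaction id {rid!r} does not resolve")

    for rxn in model.reactions:
        unresolved = [m for m in rxn.stoichiometry if m not in model._met_index]
        if unresolved:
            report.append(
                f"reaction {rxn.id}: unresolved metabolite ids {sorted(unresolved)}"
            )
            continue
        if rxn.kind == "exchange":
            if len(rxn.stoichiometry) != 1:
                report.append(
                    f"reaction {rxn.id}: exchange must touch exactly one "
                    f"metabolite, touches {len(rxn.stoichiometry)}"
                )
            else:
                (mid,) = rxn.stoichiometry
                if model.metabolite(mid).compartment != "extracellular":
                    report.append(
                        f"reaction {rxn.id}: exchange metabolite {mid} is not "
                        "extracellular"
                    )
            continue
        if rxn.id == model.biomass_id:
            continue
        if not _reaction_fully_scored(model, rxn):
            continue
        balance: dict[str, float] = {}
        charge = 0.0
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolite(mid)
            for elem, count in met.formula.items():  # type: ignore[union-attr]
                balance[elem] = balance.get(elem, 0.0) + coeff * count
            charge += coeff * met.charge  # type: ignore[operator]
        bad = {e: v for e, v in balance.items() if abs(v) > 1e-9}
        if bad:
            report.append(f"reaction {rxn.id}: element imbalance {bad}")
        if abs(charge) > 1e-9:
            report.append(f"reaction {rxn.id}: charge imbalance {charge:+g}")

    if model.biomass_id in model._rxn_index:
        biomass = model.reaction(model.biomass_id)
        if not any(c < 0 for c in biomass.stoichiometry.values()):
            report.append(
                f"reaction {model.biomass_id}: biomass consumes no metabolite"
            )
    return report


def knockout(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return an independent copy with the named reactions constrained to
    zero flux (lb = ub = 0).  The original model is untouched."""
    ids = list(reaction_ids)
    for rid in ids:
        if rid not in model._rxn_index:
            raise KeyError(f"unknown reaction id {rid!r}")
    out = model.copy()
    for rid in ids:
        rxn = out.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out
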