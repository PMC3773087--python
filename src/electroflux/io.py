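"""Model and result I/O.

Native format: a JSON document with ``metabolites``, ``reactions`` and
``roles`` sections that round-trips a :class:`MetabolicModel` losslessly and
serialises deterministically (sorted ids, sorted keys).  SBML Level 2/3 is
read through libSBML; since SBML has no notion of biomass/donor/acceptor
roles, those come from a sidecar mapping (defaulting to the reaction names
used by the published G. sulfurreducens reconstruction).  Tabular results
are written as TSV with 3-decimal numbers and '#'-prefixed provenance
header lines.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import FluxRange, FluxVector, MetabolicModel, Metabolite, Reaction

#: role reaction ids of the published G. sulfurreducens PCA reconstruction
DEFAULT_SBML_ROLES = {
    "biomass_id": "agg_GS13m_2",
    "uptake_exchange_id": "EX_ac(e)",
    "respiration_exchange_id": "EX_fe3(e)",
}

#: bound magnitude substituted for unconstrained flux directions
DEFAULT_BOUND = 1000.0


class SchemaError(ValueError):
    """A native model document violates the schema."""


class FormatError(ValueError):
    """An input file cannot be parsed."""


# ---------------------------------------------------------------------------
# native JSON format


def _model_to_doc(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": dict(sorted(m.formula.items())) if m.formula else None,
                "charge": m.charge,
                "gamma": m.gamma,
            }
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "subsystem": r.subsystem,
                "kind": r.kind,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
        "roles": {
            "biomass_id": model.biomass_id,
            "uptake_exchange_id": model.uptake_exchange_id,
            "respiration_exchange_id": model.respiration_exchange_id,
        },
    }


def write_native(model: MetabolicModel, path: str | Path) -> None:
    """Serialise a model to the native JSON document (deterministic)."""
    doc = _model_to_doc(model)
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def model_hash(model: MetabolicModel) -> str:
    """Short content hash of the deterministic serialisation, used in report
    provenance headers."""
    blob = json.dumps(_model_to_doc(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _require(doc: Mapping, key: str, path: str):
    if key not in doc:
        raise SchemaError(f"{path}: missing required field {key!r}")
    return doc[key]


def read_native(path: str | Path) -> MetabolicModel:
    """Read a native JSON model document, reporting schema violations with
    their field path."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")

    mets = []
    seen_mets: set[str] = set()
    for i, entry in enumerate(_require(doc, "metabolites", "document")):
        where = f"metabolites[{i}]"
        mid = _require(entry, "id", where)
        if mid in seen_mets:
            raise SchemaError(f"{where}.id: duplicate metabolite id {mid!r}")
        seen_mets.add(mid)
        formula = entry.get("formula")
        if formula is not None and not isinstance(formula, dict):
            raise SchemaError(f"{where}.formula: must be an element->count map")
        try:
            mets.append(
                Metabolite(
                    id=mid,
                    name=entry.get("name", ""),
                    compartment=_require(entry, "compartment", where),
                    formula={k: int(v) for k, v in formula.items()} if formula else None,
                    charge=entry.get("charge"),
                    gamma=entry.get("gamma"),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{where}: {exc}") from exc

    rxns = []
    seen_rxns: set[str] = set()
    for i, entry in enumerate(_require(doc, "reactions", "document")):
        where = f"reactions[{i}]"
        rid = _require(entry, "id", where)
        if rid in seen_rxns:
            raise SchemaError(f"{where}.id: duplicate reaction id {rid!r}")
        seen_rxns.add(rid)
        lb = float(_require(entry, "lower_bound", where))
        ub = float(_require(entry, "upper_bound", where))
        if lb > ub:
            raise SchemaError(
                f"{where}: lower_bound {lb} exceeds upper_bound {ub}"
            )
        stoich = _require(entry, "stoichiometry", where)
        if not isinstance(stoich, dict) or not stoich:
            raise SchemaError(f"{where}.stoichiometry: must be a non-empty map")
        try:
            rxns.append(
                Reaction(
                    id=rid,
                    stoichiometry={k: float(v) for k, v in stoich.items()},
                    lower_bound=lb,
                    upper_bound=ub,
                    subsystem=entry.get("subsystem", ""),
                    kind=entry.get("kind", "metabolic"),
                    name=entry.get("name", ""),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{where}: {exc}") from exc

    roles = _require(doc, "roles", "document")
    try:
        return MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_id=_require(roles, "biomass_id", "roles"),
            uptake_exchange_id=_require(roles, "uptake_exchange_id", "roles"),
            respiration_exchange_id=_require(roles, "respiration_exchange_id", "roles"),
            id=doc.get("id", "model"),
        )
    except ValueError as exc:
        raise SchemaError(str(exc)) from exc


# ---------------------------------------------------------------------------
# SBML reading

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse_formula(text: str) -> dict[str, int] | None:
    if not text:
        return None
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", text):
        return None
    out: dict[str, int] = {}
    for elem, count in _FORMULA_TOKEN.findall(text):
        out[elem] = out.get(elem, 0) + (int(count) if count else 1)
    return out


def _sbml_compartment(comp_id: str, comp_name: str) -> str:
    blob = f"{comp_id} {comp_name}".lower()
    if comp_id.lower() in ("e", "ext", "extracellular") or "extra" in blob:
        return "extracellular"
    return "cytoplasm"


def read_sbml(
    path: str | Path,
    roles: Mapping[str, str] | str | Path | None = None,
) -> MetabolicModel:
    """Read an SBML Level 2/3 model.

    ``roles`` maps the three role keys (``biomass_id``,
    ``uptake_exchange_id``, ``respiration_exchange_id``) to reaction ids —
    either a mapping or the path of a sidecar JSON file.  When omitted, the
    published-reconstruction defaults are tried.  Flux bounds come from the
    fbc package (Level 3) or kinetic-law parameters (Level 2); reactions
    without explicit bounds default to (-1000, 1000) if reversible, else
    (0, 1000).
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0 or doc.getModel() is None:
        first = doc.getError(0)
        detail = first.getMessage().strip() if first else "no model element"
        raise FormatError(f"{path}: unparseable SBML ({detail})")
    sbml_model = doc.getModel()

    if roles is None:
        roles_map = dict(DEFAULT_SBML_ROLES)
    elif isinstance(roles, (str, Path)):
        roles_map = json.loads(Path(roles).read_text())
    else:
        roles_map = dict(roles)
    for key in ("biomass_id", "uptake_exchange_id", "respiration_exchange_id"):
        if key not in roles_map:
            raise FormatError(f"roles configuration missing {key!r}")

    compartments = {
        comp.getId(): _sbml_compartment(comp.getId(), comp.getName() or "")
        for comp in sbml_model.getListOfCompartments()
    }

    def _strip(identifier: str, prefix: str) -> str:
        # COBRA-convention SBML ids carry M_/R_ prefixes; strip them so the
        # model round-trips under its own names
        return identifier[len(prefix):] if identifier.startswith(prefix) else identifier

    mets = []
    for sp in sbml_model.getListOfSpecies():
        if sp.getBoundaryCondition():
            continue  # boundary species are the implicit outside pool
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        charge = None
        if fbc_sp is not None:
            if fbc_sp.isSetChemicalFormula():
                formula = _parse_formula(fbc_sp.getChemicalFormula())
            if fbc_sp.isSetCharge():
                charge = fbc_sp.getCharge()
        if charge is None and sp.isSetCharge():
            charge = sp.getCharge()
        mets.append(
            Metabolite(
                id=_strip(sp.getId(), "M_"),
                name=sp.getName() or "",
                compartment=compartments.get(sp.getCompartment(), "cytoplasm"),
                formula=formula,
                charge=charge,
            )
        )
    met_ids = {m.id for m in mets}
    met_comp = {m.id: m.compartment for m in mets}

    fbc_model = sbml_model.getPlugin("fbc")

    def _fbc_param(pid: str) -> float | None:
        if not pid:
            return None
        par = sbml_model.getParameter(pid)
        return par.getValue() if par is not None else None

    rxns = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            mid = _strip(ref.getSpecies(), "M_")
            if mid in met_ids:
                stoich[mid] = stoich.get(mid, 0.0) - ref.getStoichiometry()
        for ref in rx.getListOfProducts():
            mid = _strip(ref.getSpecies(), "M_")
            if mid in met_ids:
                stoich[mid] = stoich.get(mid, 0.0) + ref.getStoichiometry()
        if not stoich:
            continue  # purely-boundary pseudo reaction

        lb = ub = None
        fbc_rx = rx.getPlugin("fbc")
        if fbc_rx is not None:
            lb = _fbc_param(fbc_rx.getLowerFluxBound())
            ub = _fbc_param(fbc_rx.getUpperFluxBound())
        if lb is None or ub is None:
            kl = rx.getKineticLaw()
            if kl is not None:
                for pname, target in (("LOWER_BOUND", "lb"), ("UPPER_BOUND", "ub")):
                    par = kl.getParameter(pname)
                    if par is not None:
                        if target == "lb" and lb is None:
                            lb = par.getValue()
                        elif target == "ub" and ub is None:
                            ub = par.getValue()
        reversible = rx.getReversible()
        if lb is None:
            lb = -DEFAULT_BOUND if reversible else 0.0
        if ub is None:
            ub = DEFAULT_BOUND
        lb = max(lb, -DEFAULT_BOUND)
        ub = min(ub, DEFAULT_BOUND)

        comps = {met_comp[mid] for mid in stoich}
        if len(stoich) == 1 and next(iter(comps)) == "extracellular":
            kind = "exchange"
        elif len(comps) > 1:
            kind = "transport"
        else:
            kind = "metabolic"
        rxns.append(
            Reaction(
                id=_strip(rx.getId(), "R_"),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                subsystem="",
                kind=kind,
                name=rx.getName() or "",
            )
        )

    rxn_ids = {r.id for r in rxns}
    missing = [v for v in roles_map.values() if v not in rxn_ids]
    if missing:
        raise FormatError(
            f"{path}: role reaction ids {missing} not present in the SBML model; "
            "supply a roles mapping"
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_id=roles_map["biomass_id"],
        uptake_exchange_id=roles_map["uptake_exchange_id"],
        respiration_exchange_id=roles_map["respiration_exchange_id"],
        id=sbml_model.getId() or "sbml_model",
    )


# ---------------------------------------------------------------------------
# TSV report writing


def _format(value) -> str:
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, float)):
        return f"{value:.3f}"
    return str(value)


def write_flux_table(
    result: FluxVector | FluxRange | pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a flux result as TSV: '#' provenance header lines, a column
    header row, then 3-decimal numbers in deterministic row order."""
    lines: list[str] = []
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}: {value}")
    if isinstance(result, FluxVector):
        lines.append("reaction\tflux")
        for rid in sorted(result.values):
            lines.append(f"{rid}\t{_format(result.values[rid])}")
    elif isinstance(result, FluxRange):
        lines.append("reaction\tmin_flux\tmax_flux")
        for rid in sorted(result.ranges):
            lo, hi = result.ranges[rid]
            lines.append(f"{rid}\t{_format(lo)}\t{_format(hi)}")
    elif isinstance(result, pd.DataFrame):
        lines.append("\t".join(map(str, result.columns)))
        for row in result.itertuples(index=False):
            lines.append("\t".join(_format(v) for v in row))
    else:
        raise TypeError(f"cannot serialise {type(result).__name__} as a flux table")
    Path(path).write_text("\n".join(lines) + "\n")
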