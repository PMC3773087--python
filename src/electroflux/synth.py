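"""Generator of small, fully balanced Geobacter-like toy models.

The emitted network mirrors the qualitative architecture of acetate-fuelled,
Fe(III)-respiring metabolism:

* acetate exchange, proton-symport uptake, and ATP-dependent activation to
  acetyl-CoA;
* a lumped TCA route oxidising acetyl-CoA to 2 CO2 while loading 2 NADH and
  2 reduced ferredoxin (8 electrons per acetate);
* redundant acetyl-CoA <-> pyruvate interconversion: pyruvate dehydrogenase,
  formate-producing pyruvate formate-lyase, and ferredoxin-driven pyruvate
  synthase, plus a formate dehydrogenase feeding the quinone pool;
* a simplified electron transport chain (proton-pumping NADH dehydrogenase,
  ferredoxin:quinone reductase, cytochrome-c reductase at 2 e- per quinol,
  and a 1-electron Fe(III) reductase with an Fe3+/Fe2+ exchange pair);
* ATP synthase, a fixed ATP maintenance drain, an optional futile
  ATP-dissipation cycle, and a proton leak;
* a biomass pseudo-reaction drawing acetyl-CoA, pyruvate and ATP;
* electron-leaking secretion transporters ("leaks") for formate, pyruvate,
  amino-acid-like species and H2.

Every internal reaction conserves the degree of reduction exactly, so the
maximum respiration at zero growth is forced by electron conservation to
gamma_acetate * uptake = 8 x uptake — with the default uptake of
13.630 mmol/gDW/h, 109.040 mmol/gDW/h.

Leak transporters are unbounded but energized: each secretion unit costs a
small, strictly increasing number of periplasmic protons.  At minimum
respiration the proton-motive force is fully committed to ATP demand, so
the leak allocation is the unique cost-ordered optimum, the minimum
respiration is set by the ATP cost of growth (hence non-decreasing in the
growth rate, mirroring the published sweep's structure), and the iterative
knockout order is analytically known (see ToyGroundTruth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MetabolicModel, Metabolite, Reaction

#: degree of reduction of acetate (C2H3O2-): 4*2 + 3 - 2*2 - (-1)
GAMMA_ACETATE = 8.0

LEAK_KINDS = ("formate", "pyruvate", "h2")  # plus generic_aa_<n>


class GenerationError(ValueError):
    """Inconsistent toy parameters."""


@dataclass
class ToyParams:
    """Study conditions for the synthetic toy model.

    The default acetate uptake (13.630 mmol/gDW/h) is the fixed donor uptake
    used throughout the respiration sweeps; maintenance ATP and biomass
    draws set the energy/carbon cost of growth.
    """

    uptake_rate: float = 13.630
    biomass_atp_cost: float = 60.0
    biomass_precursor_draws: dict[str, float] = field(
        default_factory=lambda: {"accoa_c": 30.0, "pyr_c": 10.0}
    )
    leaks: tuple[str, ...] = ("formate", "pyruvate")
    include_redundant_pdh_routes: bool = True
    include_futile_cycle: bool = True
    default_bound: float = 1000.0
    maintenance_atp: float = 0.45
    seed: int = 0
    randomize: bool = False  # randomize leak costs and byproduct stoichiometries

    def __post_init__(self) -> None:
        if self.uptake_rate <= 0:
            raise GenerationError("uptake_rate must be positive")
        for leak in self.leaks:
            if leak not in LEAK_KINDS and not leak.startswith("generic_aa_"):
                raise GenerationError(f"unknown leak kind {leak!r}")
        if len(set(self.leaks)) != len(self.leaks):
            raise GenerationError("duplicate leak kinds")


@dataclass
class ToyGroundTruth:
    """Analytic ground truth for the emitted model.

    ``planted_leak_order`` is the knockout order the iterative designer must
    recover: carbon-backbone leaks (amino-acid-like byproducts by descending
    degree of reduction, then pyruvate) dominate the electron dump and come
    first; ferredoxin-limited leaks (formate, H2) follow in ascending
    secretion-cost order.
    """

    max_respiration_at_zero_growth: float
    planted_leak_order: list[str]  # extracellular metabolite ids
    electrons_per_leak_unit: dict[str, float]
    leak_transporters: dict[str, str]  # metabolite id -> transporter id
    leak_proton_costs: dict[str, float]  # metabolite id -> h_e per secretion unit
    biomass_electron_cost: float
    #: catabolic reactions whose carrier loading drives respiration; safe to
    #: compare across alternate optima (redundant-route fluxes are not)
    reducing_equivalent_reactions: list[str] = field(default_factory=lambda: ["TCA"])


def _met(mid, name, comp, formula=None, charge=None, gamma=None):
    return Metabolite(mid, name, comp, formula, charge, gamma)


def make_toy_model(params: ToyParams | None = None) -> tuple[MetabolicModel, ToyGroundTruth]:
    """Build the toy model and its analytic ground truth."""
    p = params or ToyParams()
    rng = np.random.default_rng(p.seed)

    mets: list[Metabolite] = [
        _met("ac_e", "acetate", "extracellular", {"C": 2, "H": 3, "O": 2}, -1),
        _met("ac_c", "acetate", "cytoplasm", {"C": 2, "H": 3, "O": 2}, -1),
        _met("co2_e", "CO2", "extracellular", {"C": 1, "O": 2}, 0),
        _met("co2_c", "CO2", "cytoplasm", {"C": 1, "O": 2}, 0),
        _met("h2o_e", "water", "extracellular", {"H": 2, "O": 1}, 0),
        _met("h2o_c", "water", "cytoplasm", {"H": 2, "O": 1}, 0),
        _met("h_e", "proton", "extracellular", {"H": 1}, 1),
        _met("h_c", "proton", "cytoplasm", {"H": 1}, 1),
        _met("fe3_e", "Fe(III)", "extracellular", None, None, 0.0),
        _met("fe2_e", "Fe(II)", "extracellular", None, None, 1.0),
        _met("accoa_c", "acetyl-CoA (acetyl unit)", "cytoplasm", None, None, 8.0),
        _met("pyr_c", "pyruvate", "cytoplasm", {"C": 3, "H": 3, "O": 3}, -1),
        _met("nad_c", "NAD+", "cytoplasm", None, None, 0.0),
        _met("nadh_c", "NADH", "cytoplasm", None, None, 2.0),
        _met("mqn_c", "menaquinone", "cytoplasm", None, None, 0.0),
        _met("mql_c", "menaquinol", "cytoplasm", None, None, 2.0),
        _met("fdox_c", "oxidised ferredoxin", "cytoplasm", None, None, 0.0),
        _met("fdred_c", "reduced ferredoxin", "cytoplasm", None, None, 2.0),
        _met("cytc_ox_c", "cytochrome c (ox)", "cytoplasm", None, None, 0.0),
        _met("cytc_red_c", "cytochrome c (red)", "cytoplasm", None, None, 1.0),
        _met("atp_c", "ATP", "cytoplasm", None, None, 0.0),
        _met("adp_c", "ADP", "cytoplasm", None, None, 0.0),
        _met("pi_c", "phosphate", "cytoplasm", None, None, 0.0),
    ]
    B = p.default_bound
    rxns: list[Reaction] = [
        Reaction("EX_ac", {"ac_e": -1}, -B, B, "exchange", "exchange", "acetate exchange"),
        Reaction("EX_co2", {"co2_e": -1}, -B, B, "exchange", "exchange", "CO2 exchange"),
        Reaction("EX_h2o", {"h2o_e": -1}, -B, B, "exchange", "exchange", "water exchange"),
        Reaction("EX_fe3", {"fe3_e": -1}, -B, 0, "exchange", "exchange", "Fe(III) exchange"),
        Reaction("EX_fe2", {"fe2_e": -1}, 0, B, "exchange", "exchange", "Fe(II) exchange"),
        Reaction(
            "ACt",
            {"ac_e": -1, "h_e": -1, "ac_c": 1, "h_c": 1},
            0, B, "transport", "transport", "acetate proton symport",
        ),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, -B, B, "transport", "transport", "CO2 diffusion"),
        Reaction("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -B, B, "transport", "transport", "water diffusion"),
        Reaction(
            "ACS",
            {"ac_c": -1, "atp_c": -1, "accoa_c": 1, "adp_c": 1, "pi_c": 1},
            0, B, "central metabolism", "metabolic", "acetate activation to acetyl-CoA",
        ),
        Reaction(
            "TCA",
            {
                "accoa_c": -1, "nad_c": -2, "fdox_c": -2, "h2o_c": -2,
                "co2_c": 2, "nadh_c": 2, "fdred_c": 2,
            },
            0, B, "central metabolism", "metabolic", "lumped TCA cycle",
        ),
        Reaction(
            "POR",
            {"accoa_c": -1, "co2_c": -1, "fdred_c": -1, "pyr_c": 1, "fdox_c": 1},
            0, B, "central metabolism", "metabolic", "pyruvate synthase (ferredoxin)",
        ),
        Reaction(
            "NDH",
            {"nadh_c": -1, "mqn_c": -1, "h_c": -2, "nad_c": 1, "mql_c": 1, "h_e": 2},
            0, B, "energy metabolism", "metabolic", "NADH dehydrogenase (proton pumping)",
        ),
        Reaction(
            "FQR",
            {"fdred_c": -1, "mqn_c": -1, "fdox_c": 1, "mql_c": 1},
            0, B, "energy metabolism", "metabolic", "ferredoxin:quinone reductase",
        ),
        Reaction(
            "CYTBC",
            {"mql_c": -1, "cytc_ox_c": -2, "h_c": -2, "mqn_c": 1, "cytc_red_c": 2, "h_e": 2},
            0, B, "energy metabolism", "metabolic", "cytochrome-c reductase",
        ),
        Reaction(
            "FE3R",
            {"cytc_red_c": -1, "fe3_e": -1, "cytc_ox_c": 1, "fe2_e": 1},
            0, B, "energy metabolism", "transport", "Fe(III) reductase",
        ),
        Reaction(
            "ATPS",
            {"adp_c": -1, "pi_c": -1, "h_e": -3, "atp_c": 1, "h2o_c": 1, "h_c": 3},
            0, B, "energy metabolism", "metabolic", "ATP synthase",
        ),
        Reaction(
            "ATPM",
            {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
            p.maintenance_atp, p.maintenance_atp,
            "energy metabolism", "metabolic", "non-growth ATP maintenance",
        ),
        Reaction(
            "LEAK_H",
            {"h_e": -1, "h_c": 1},
            0, B, "energy metabolism", "metabolic", "proton leak",
        ),
    ]
    if p.include_futile_cycle:
        rxns.append(
            Reaction(
                "FUTILE",
                {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1},
                0, B, "energy metabolism", "metabolic", "ATP-dissipating futile cycle",
            )
        )
    if p.include_redundant_pdh_routes:
        mets.append(_met("for_c", "formate", "cytoplasm", {"C": 1, "H": 1, "O": 2}, -1))
        rxns += [
            Reaction(
                "PDH",
                {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "co2_c": 1, "nadh_c": 1},
                0, B, "central metabolism", "metabolic", "pyruvate dehydrogenase",
            ),
            Reaction(
                "PFL",
                {"pyr_c": -1, "accoa_c": 1, "for_c": 1},
                0, B, "central metabolism", "metabolic", "pyruvate formate-lyase",
            ),
            Reaction(
                "FDH",
                {"for_c": -1, "mqn_c": -1, "co2_c": 1, "mql_c": 1},
                0, B, "energy metabolism", "metabolic", "formate dehydrogenase",
            ),
        ]

    # biomass: consumes precursors + ATP, regenerates ADP/Pi
    for precursor in p.biomass_precursor_draws:
        if precursor not in {m.id for m in mets}:
            raise GenerationError(f"biomass draws on absent precursor {precursor!r}")
    biomass_stoich: dict[str, float] = {
        mid: -coeff for mid, coeff in p.biomass_precursor_draws.items()
    }
    biomass_stoich.update(
        {
            "atp_c": -p.biomass_atp_cost,
            "h2o_c": -p.biomass_atp_cost,
            "adp_c": p.biomass_atp_cost,
            "pi_c": p.biomass_atp_cost,
        }
    )
    rxns.append(
        Reaction("BIOMASS", biomass_stoich, 0, B, "biomass", "metabolic", "biomass synthesis")
    )

    # ----- electron-leaking secretion transporters -------------------------
    # each secretion unit is energized: it costs c_i periplasmic protons,
    # with the per-electron cost c_i/gamma_i strictly increasing along the
    # leak list.  At minimum respiration the proton-motive force is fully
    # committed, so the leak allocation is unique and cost-ordered.
    per_electron_costs = [
        0.02 * (i + 1) + (float(rng.uniform(0.0, 0.015)) if p.randomize else 0.0)
        for i in range(len(p.leaks))
    ]

    electrons_per_unit: dict[str, float] = {}
    leak_transporters: dict[str, str] = {}
    leak_costs: dict[str, float] = {}
    leak_class: dict[str, str] = {}  # carbon-backbone vs ferredoxin-limited
    leak_index: dict[str, int] = {}

    for i, leak in enumerate(p.leaks):
        if leak == "formate":
            if not p.include_redundant_pdh_routes:
                raise GenerationError(
                    "formate leak requires the redundant formate-producing route"
                )
            gamma, met_e, trans = 2.0, "for_e", "FORt"
            cost = round(per_electron_costs[i] * gamma, 6)
            mets.append(_met("for_e", "formate", "extracellular", {"C": 1, "H": 1, "O": 2}, -1))
            rxns.append(
                Reaction(
                    "FORt",
                    {"for_c": -1, "h_e": -cost, "for_e": 1, "h_c": cost},
                    0, B, "transport", "transport", "energized formate secretion",
                )
            )
            klass = "ferredoxin"
        elif leak == "pyruvate":
            gamma, met_e, trans = 10.0, "pyr_e", "PYRt"
            cost = round(per_electron_costs[i] * gamma, 6)
            mets.append(_met("pyr_e", "pyruvate", "extracellular", {"C": 3, "H": 3, "O": 3}, -1))
            rxns.append(
                Reaction(
                    "PYRt",
                    {"pyr_c": -1, "h_e": -cost, "pyr_e": 1, "h_c": cost},
                    0, B, "transport", "transport", "energized pyruvate secretion",
                )
            )
            klass = "carbon"
        elif leak == "h2":
            gamma, met_e, trans = 2.0, "h2_e", "H2t"
            cost = round(per_electron_costs[i] * gamma, 6)
            mets += [
                _met("h2_c", "hydrogen", "cytoplasm", {"H": 2}, 0),
                _met("h2_e", "hydrogen", "extracellular", {"H": 2}, 0),
            ]
            rxns += [
                Reaction(
                    "HYD",
                    {"fdred_c": -1, "fdox_c": 1, "h2_c": 1},
                    0, B, "energy metabolism", "metabolic", "ferredoxin hydrogenase",
                ),
                Reaction(
                    "H2t",
                    {"h2_c": -1, "h_e": -cost, "h2_e": 1, "h_c": cost},
                    0, B, "transport", "transport", "energized H2 release",
                ),
            ]
            klass = "ferredoxin"
        else:  # generic_aa_<n>: amino-acid-like byproduct lumped from acetyl units
            n = int(leak.split("generic_aa_")[1])
            gamma = 8.0 * (1 + n)
            met_e, trans = f"aa{n}_e", f"AA{n}t"
            cost = round(per_electron_costs[i] * gamma, 6)
            mets += [
                _met(f"aa{n}_c", f"amino-acid-like byproduct {n}", "cytoplasm", None, None, gamma),
                _met(f"aa{n}_e", f"amino-acid-like byproduct {n}", "extracellular", None, None, gamma),
            ]
            rxns += [
                Reaction(
                    f"AA{n}_SYN",
                    {"accoa_c": -(1.0 + n), f"aa{n}_c": 1},
                    0, B, "amino acid metabolism", "metabolic",
                    f"byproduct {n} synthesis",
                ),
                Reaction(
                    f"AA{n}t",
                    {f"aa{n}_c": -1, "h_e": -cost, f"aa{n}_e": 1, "h_c": cost},
                    0, B, "transport", "transport", f"energized byproduct {n} secretion",
                ),
            ]
            klass = "carbon"
        rxns.append(
            Reaction(
                f"EX_{met_e.rsplit('_', 1)[0]}", {met_e: -1}, 0, B,
                "exchange", "exchange", f"{met_e} exchange",
            )
        )
        electrons_per_unit[met_e] = gamma
        leak_transporters[met_e] = trans
        leak_costs[met_e] = cost
        leak_class[met_e] = klass
        leak_index[met_e] = i

    # planted knockout order: carbon-backbone leaks carry the bulk of the
    # electron dump (amino-acid byproducts by descending gamma, then
    # pyruvate); ferredoxin-limited leaks follow in ascending-cost order
    carbon = sorted(
        (m for m, k in leak_class.items() if k == "carbon"),
        key=lambda m: (-electrons_per_unit[m], leak_index[m]),
    )
    ferredoxin = sorted(
        (m for m, k in leak_class.items() if k == "ferredoxin"),
        key=lambda m: leak_index[m],
    )
    planted_order = carbon + ferredoxin

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_id="BIOMASS",
        uptake_exchange_id="EX_ac",
        respiration_exchange_id="EX_fe3",
        id=f"toy_seed{p.seed}" if p.randomize else "toy",
    )
    biomass_e = sum(
        coeff * {"accoa_c": 8.0, "pyr_c": 10.0}.get(mid, 0.0)
        for mid, coeff in p.biomass_precursor_draws.items()
    )
    truth = ToyGroundTruth(
        max_respiration_at_zero_growth=GAMMA_ACETATE * p.uptake_rate,
        planted_leak_order=planted_order,
        electrons_per_leak_unit=electrons_per_unit,
        leak_transporters=leak_transporters,
        leak_proton_costs=leak_costs,
        biomass_electron_cost=biomass_e,
    )
    return model, truth


# ---------------------------------------------------------------------------
# named fixtures


def make_minimal_chain(uptake_rate: float = 13.630) -> tuple[MetabolicModel, ToyGroundTruth]:
    """Donor -> acceptor only: acetate fully oxidised in one lumped step with
    all 8 electrons delivered to Fe(III).  Small enough for exhaustive
    vertex-enumeration oracles."""
    mets = [
        _met("ac_e", "acetate", "extracellular", {"C": 2, "H": 3, "O": 2}, -1),
        _met("ac_c", "acetate", "cytoplasm", {"C": 2, "H": 3, "O": 2}, -1),
        _met("co2_e", "CO2", "extracellular", {"C": 1, "O": 2}, 0),
        _met("co2_c", "CO2", "cytoplasm", {"C": 1, "O": 2}, 0),
        _met("h2o_e", "water", "extracellular", {"H": 2, "O": 1}, 0),
        _met("h2o_c", "water", "cytoplasm", {"H": 2, "O": 1}, 0),
        _met("h_e", "proton", "extracellular", {"H": 1}, 1),
        _met("h_c", "proton", "cytoplasm", {"H": 1}, 1),
        _met("fe3_e", "Fe(III)", "extracellular", None, None, 0.0),
        _met("fe2_e", "Fe(II)", "extracellular", None, None, 1.0),
    ]
    B = 1000.0
    rxns = [
        Reaction("EX_ac", {"ac_e": -1}, -B, B, "exchange", "exchange"),
        Reaction("EX_co2", {"co2_e": -1}, -B, B, "exchange", "exchange"),
        Reaction("EX_h2o", {"h2o_e": -1}, -B, B, "exchange", "exchange"),
        Reaction("EX_h", {"h_e": -1}, -B, B, "exchange", "exchange"),
        Reaction("EX_fe3", {"fe3_e": -1}, -B, 0, "exchange", "exchange"),
        Reaction("EX_fe2", {"fe2_e": -1}, 0, B, "exchange", "exchange"),
        Reaction("ACt", {"ac_e": -1, "h_e": -1, "ac_c": 1, "h_c": 1}, 0, B, "transport", "transport"),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, -B, B, "transport", "transport"),
        Reaction("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -B, B, "transport", "transport"),
        Reaction("Ht", {"h_c": -1, "h_e": 1}, -B, B, "transport", "transport"),
        Reaction(
            "AC_OX",
            {
                "ac_c": -1, "h2o_c": -2, "fe3_e": -8,
                "co2_c": 2, "fe2_e": 8, "h_c": 7,
            },
            0, B, "central metabolism", "transport", "complete acetate oxidation",
        ),
        Reaction("BIOMASS", {"ac_c": -1}, 0, B, "biomass", "metabolic"),
    ]
    model = MetabolicModel(mets, rxns, "BIOMASS", "EX_ac", "EX_fe3", id="minimal_chain")
    truth = ToyGroundTruth(
        max_respiration_at_zero_growth=GAMMA_ACETATE * uptake_rate,
        planted_leak_order=[],
        electrons_per_leak_unit={},
        leak_transporters={},
        leak_proton_costs={},
        biomass_electron_cost=GAMMA_ACETATE,
    )
    return model, truth


def make_fixture_suite() -> dict[str, tuple[MetabolicModel, ToyGroundTruth]]:
    """Deterministic named fixture models with ground-truth annotations.

    minimal_chain: donor -> acceptor only; wild_toy: all features including
    leaks; ideal_toy: wild_toy with every leak transporter pre-knocked;
    degenerate_toy: wild_toy plus a duplicated NADH dehydrogenase, so FVA
    slack is guaranteed among internal reactions even at a fixed objective.
    """
    from .core import knockout  # local import to avoid cycle at module load

    suite: dict[str, tuple[MetabolicModel, ToyGroundTruth]] = {}
    suite["minimal_chain"] = make_minimal_chain()

    wild, wild_truth = make_toy_model(ToyParams())
    suite["wild_toy"] = (wild, wild_truth)

    ideal = knockout(wild, list(wild_truth.leak_transporters.values()))
    ideal.id = "ideal_toy"
    ideal_truth = ToyGroundTruth(
        max_respiration_at_zero_growth=wild_truth.max_respiration_at_zero_growth,
        planted_leak_order=[],
        electrons_per_leak_unit=wild_truth.electrons_per_leak_unit,
        leak_transporters={},
        leak_proton_costs={},
        biomass_electron_cost=wild_truth.biomass_electron_cost,
    )
    suite["ideal_toy"] = (ideal, ideal_truth)

    degen, degen_truth = make_toy_model(ToyParams())
    degen.id = "degenerate_toy"
    ndh = degen.reaction("NDH")
    degen.reactions.append(
        Reaction(
            "NDH2", dict(ndh.stoichiometry), ndh.lower_bound, ndh.upper_bound,
            ndh.subsystem, ndh.kind, "NADH dehydrogenase (duplicate isozyme)",
        )
    )
    degen._reindex()
    suite["degenerate_toy"] = (degen, degen_truth)
    return suite
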