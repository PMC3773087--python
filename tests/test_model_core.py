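import numpy as np
import pytest

from electroflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    StructuralError,
    fva_all,
    knockout,
    solve_fba,
    stoichiometric_matrix,
    validate_model,
)


def tiny_model(**overrides):
    """One-reaction A -> B scaffold used for structural edge cases."""
    kwargs = dict(
        metabolites=[
            Metabolite("A", compartment="cytoplasm"),
            Metabolite("B", compartment="cytoplasm"),
            Metabolite("X", compartment="extracellular"),
        ],
        reactions=[
            Reaction("conv", {"A": -1, "B": 1}, 0, 10),
            Reaction("EX_X", {"X": -1}, -10, 10, kind="exchange"),
            Reaction("growth", {"B": -1}, 0, 10),
        ],
        biomass_id="growth",
        uptake_exchange_id="EX_X",
        respiration_exchange_id="EX_X",
    )
    kwargs.update(overrides)
    return MetabolicModel(**kwargs)


class TestStoichiometricMatrix:
    def test_single_conversion_column(self):
        model = tiny_model()
        S = stoichiometric_matrix(model)
        assert S.shape == (3, 3)
        a, b = model._met_index["A"], model._met_index["B"]
        j = model._rxn_index["conv"]
        assert S[a, j] == -1 and S[b, j] == 1

    def test_internal_columns_element_balanced_on_toy(self, wild):
        """Fully-specified internal reactions conserve every element."""
        model, _ = wild
        S = stoichiometric_matrix(model)
        checked = 0
        for j, rxn in enumerate(model.reactions):
            mets = [model.metabolite(mid) for mid in rxn.stoichiometry]
            if rxn.kind == "exchange" or rxn.id == model.biomass_id:
                continue
            if any(m.formula is None for m in mets):
                continue
            balance: dict[str, float] = {}
            for mid, coeff in rxn.stoichiometry.items():
                for elem, count in model.metabolite(mid).formula.items():
                    balance[elem] = balance.get(elem, 0.0) + coeff * count
            assert all(abs(v) < 1e-9 for v in balance.values()), rxn.id
            # and the matrix column is exactly the stoichiometry
            for mid, coeff in rxn.stoichiometry.items():
                assert S[model._met_index[mid], j] == coeff
            checked += 1
        assert checked >= 5

    def test_column_is_linear_in_stoichiometry(self):
        model = tiny_model()
        scaled = tiny_model(
            reactions=[
                Reaction("conv", {"A": -2.5, "B": 2.5}, 0, 10),
                Reaction("EX_X", {"X": -1}, -10, 10, kind="exchange"),
                Reaction("growth", {"B": -1}, 0, 10),
            ]
        )
        j = model._rxn_index["conv"]
        np.testing.assert_allclose(
            stoichiometric_matrix(scaled)[:, j],
            2.5 * stoichiometric_matrix(model)[:, j],
        )

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(StructuralError, match="empty stoichiometry"):
            Reaction("bad", {})

    def test_unresolved_metabolite_names_reaction(self):
        model = tiny_model()
        model.reactions[0].stoichiometry["ghost"] = 1.0
        with pytest.raises(StructuralError, match="conv.*ghost"):
            stoichiometric_matrix(model)


class TestValidateModel:
    def test_toy_models_are_clean(self, suite):
        for name, (model, _) in suite.items():
            assert validate_model(model) == [], name

    def test_perturbed_coefficient_flags_one_imbalance(self, wild):
        model, _ = wild
        broken = model.copy()
        broken.reaction("ACt").stoichiometry["h_c"] = 2.0  # plant a defect
        report = validate_model(broken)
        assert report and all("ACt" in line for line in report)

    def test_missing_role_reported(self, wild):
        model, _ = wild
        broken = model.copy()
        broken.respiration_exchange_id = "EX_missing"
        report = validate_model(broken)
        assert any("respiration" in line for line in report)

    def test_duplicate_metabolite_id_rejected(self):
        with pytest.raises(StructuralError, match="duplicate"):
            tiny_model(
                metabolites=[
                    Metabolite("A"),
                    Metabolite("A"),
                    Metabolite("X", compartment="extracellular"),
                ]
            )

    def test_exchange_must_be_single_extracellular(self):
        model = tiny_model(
            reactions=[
                Reaction("conv", {"A": -1, "B": 1}, 0, 10),
                Reaction("EX_X", {"X": -1, "A": 1}, -10, 10, kind="exchange"),
                Reaction("growth", {"B": -1}, 0, 10),
            ]
        )
        assert any("exactly one" in line for line in validate_model(model))


class TestKnockout:
    def test_empty_knockout_is_identity(self, wild):
        model, _ = wild
        same = knockout(model, [])
        assert [(r.lower_bound, r.upper_bound) for r in same.reactions] == [
            (r.lower_bound, r.upper_bound) for r in model.reactions
        ]

    def test_unknown_id_named_in_error(self, wild):
        model, _ = wild
        with pytest.raises(KeyError, match="GHOSTt"):
            knockout(model, ["GHOSTt"])

    def test_original_untouched(self, wild):
        model, truth = wild
        transporter = next(iter(truth.leak_transporters.values()))
        before = model.reaction(transporter).upper_bound
        knockout(model, [transporter])
        assert model.reaction(transporter).upper_bound == before

    def test_biomass_knockout_kills_growth(self, wild, config):
        model, _ = wild
        dead = knockout(model, [model.biomass_id])
        outcome = solve_fba(dead, model.biomass_id, "maximize", config.uptake_fix(model))
        assert outcome.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_knockout_never_enlarges_flux_ranges(self, wild, config, wild_vgr_max):
        """Deleting a reaction shrinks (or keeps) every FVA range."""
        model, truth = wild
        fixed = config.uptake_fix(model)
        fixed[model.biomass_id] = 0.1 * wild_vgr_max
        before = fva_all(model, fixed)
        after = fva_all(knockout(model, [truth.leak_transporters["for_e"]]), fixed)
        for rid, (lo_a, hi_a) in after.items():
            lo_b, hi_b = before[rid]
            assert lo_a >= lo_b - 1e-7 and hi_a <= hi_b + 1e-7, rid

    def test_leak_knockout_raises_min_respiration(self, wild, config, wild_vgr_max):
        from electroflux.sweep import respiration_range

        model, truth = wild
        v_gr = 0.1 * wild_vgr_max
        lo_before, _ = respiration_range(model, v_gr, config)
        ko = knockout(model, list(truth.leak_transporters.values()))
        lo_after, _ = respiration_range(ko, v_gr, config)
        assert lo_after > lo_before + 1.0
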