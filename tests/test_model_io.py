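import json

import pytest

from electroflux import (
    FluxRange,
    FluxVector,
    SweepConfig,
    make_toy_model,
    optimal_growth,
    read_native,
    read_sbml,
    respiration_table,
    solve_fba,
    write_flux_table,
    write_native,
)
from electroflux.io import FormatError, SchemaError, _model_to_doc

cobra = pytest.importorskip("cobra")


def to_cobra(model):
    """Rebuild our model as a cobrapy model (independent representation)."""
    cm = cobra.Model(model.id)
    comp = {"cytoplasm": "c", "extracellular": "e"}
    mets = {}
    for m in model.metabolites:
        cmet = cobra.Metabolite(m.id, compartment=comp[m.compartment], name=m.name)
        if m.formula is not None:
            cmet.formula = "".join(f"{el}{n}" for el, n in sorted(m.formula.items()))
        if m.charge is not None:
            cmet.charge = m.charge
        mets[m.id] = cmet
    for r in model.reactions:
        crx = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([crx])
        crx.add_metabolites({mets[mid]: coeff for mid, coeff in r.stoichiometry.items()})
    return cm


@pytest.fixture(scope="module")
def sbml_toy(tmp_path_factory):
    """SBML export of the default toy, written by cobrapy."""
    model, _ = make_toy_model()
    path = tmp_path_factory.mktemp("sbml") / "toy.xml"
    cobra.io.write_sbml_model(to_cobra(model), str(path))
    return model, path


ROLES = {
    "biomass_id": "BIOMASS",
    "uptake_exchange_id": "EX_ac",
    "respiration_exchange_id": "EX_fe3",
}


class TestNativeRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 17])
    def test_lossless_round_trip(self, tmp_path, seed):
        from electroflux import ToyParams

        model, _ = make_toy_model(ToyParams(seed=seed, randomize=seed > 0))
        path = tmp_path / "toy.json"
        write_native(model, path)
        again = read_native(path)
        assert _model_to_doc(again) == _model_to_doc(model)

    def test_serialisation_deterministic(self, tmp_path, wild):
        model, _ = wild
        a, b = tmp_path / "a.json", tmp_path / "b.json"
        write_native(model, a)
        write_native(model, b)
        assert a.read_bytes() == b.read_bytes()

    def test_duplicate_metabolite_id_rejected_with_path(self, tmp_path, wild):
        model, _ = wild
        doc = _model_to_doc(model)
        doc["metabolites"].append(dict(doc["metabolites"][0]))
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match=r"metabolites\[\d+\]"):
            read_native(path)

    def test_inverted_bounds_rejected(self, tmp_path, wild):
        model, _ = wild
        doc = _model_to_doc(model)
        doc["reactions"][0]["lower_bound"] = 5.0
        doc["reactions"][0]["upper_bound"] = -5.0
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="lower_bound"):
            read_native(path)

    def test_invalid_json_is_format_error(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(FormatError):
            read_native(path)


class TestReadSBML:
    def test_round_trip_preserves_structure(self, sbml_toy):
        model, path = sbml_toy
        loaded = read_sbml(path, ROLES)
        assert sorted(loaded.reaction_ids()) == sorted(model.reaction_ids())
        assert sorted(loaded.metabolite_ids()) == sorted(model.metabolite_ids())
        for rxn in model.reactions:
            twin = loaded.reaction(rxn.id)
            assert twin.stoichiometry == pytest.approx(rxn.stoichiometry)
            assert twin.lower_bound == rxn.lower_bound
            assert twin.upper_bound == rxn.upper_bound
        acetate = loaded.metabolite("ac_e")
        assert acetate.compartment == "extracellular"
        assert acetate.formula == {"C": 2, "H": 3, "O": 2} and acetate.charge == -1

    def test_sbml_and_native_readers_agree_on_fba(self, sbml_toy, tmp_path):
        model, path = sbml_toy
        config = SweepConfig()
        native_path = tmp_path / "toy.json"
        write_native(model, native_path)
        from_native = optimal_growth(read_native(native_path), config)
        from_sbml = optimal_growth(read_sbml(path, ROLES), config)
        assert from_sbml == pytest.approx(from_native, abs=1e-9)

    def test_truncated_file_is_format_error(self, sbml_toy, tmp_path):
        _, path = sbml_toy
        stub = tmp_path / "broken.xml"
        stub.write_text(path.read_text()[: len(path.read_text()) // 2])
        with pytest.raises(FormatError):
            read_sbml(stub, ROLES)

    def test_missing_role_reaction_is_error(self, sbml_toy):
        _, path = sbml_toy
        with pytest.raises(FormatError, match="GHOST"):
            read_sbml(path, {**ROLES, "biomass_id": "GHOST"})


class TestCobraCrossCheck:
    """cobrapy as an independent FBA/FVA oracle on the same network."""

    def test_fba_objective_matches_cobra(self, wild, config):
        model, _ = wild
        cm = to_cobra(model)
        cm.reactions.EX_ac.bounds = (-config.uptake_rate, -config.uptake_rate)
        cm.objective = "BIOMASS"
        expected = cm.optimize().objective_value
        ours = optimal_growth(model, config)
        assert ours == pytest.approx(expected, abs=1e-6)

    def test_respiration_fva_matches_cobra(self, wild, config, wild_vgr_max):
        from electroflux.sweep import respiration_range

        model, _ = wild
        v_gr = 0.5 * wild_vgr_max
        cm = to_cobra(model)
        cm.reactions.EX_ac.bounds = (-config.uptake_rate, -config.uptake_rate)
        cm.reactions.BIOMASS.bounds = (v_gr, v_gr)
        cm.objective = "EX_fe3"
        cm.objective_direction = "min"
        signed_min = cm.optimize().objective_value
        cm.objective_direction = "max"
        signed_max = cm.optimize().objective_value
        ours = respiration_range(model, v_gr, config)
        assert ours == pytest.approx((-signed_max, -signed_min), abs=1e-6)


class TestWriteFluxTable:
    def test_respiration_table_rows_and_formatting(self, tmp_path, wild, config):
        model, _ = wild
        table = respiration_table(model, config)
        path = tmp_path / "table.tsv"
        write_flux_table(table, path, {"uptake": config.uptake_rate})
        lines = path.read_text().splitlines()
        assert lines[0] == "# uptake: 13.63"
        assert lines[1] == "v_gr\tv_res_min\tv_res_max"
        data = lines[2:]
        assert len(data) == len(config.k_grid)
        assert data[-1].split("\t") == ["0.000", "29.361", "109.040"]

    def test_empty_range_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_flux_table(FluxRange({}), path)
        assert path.read_text() == "reaction\tmin_flux\tmax_flux\n"

    def test_flux_vector_sorted_three_decimals(self, tmp_path):
        vec = FluxVector({"b": 1.23456, "a": -2.0}, "a", -2.0)
        path = tmp_path / "vec.tsv"
        write_flux_table(vec, path)
        assert path.read_text().splitlines()[1:] == ["a\t-2.000", "b\t1.235"]

    def test_unsupported_type_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            write_flux_table(object(), tmp_path / "x.tsv")
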