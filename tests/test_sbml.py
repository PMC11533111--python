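"""SBML export/import: structure, consistency, round-trip identity and
simulation parity."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lxml import etree

from pbpksim.model import BloodPool, ExposureScenario, ModelMetadata, PBPKModel, Tissue
from pbpksim.sbml import (
    MATHML_NS,
    SBML_NS,
    UnsupportedModelError,
    check_consistency,
    from_sbml,
    read_sbml,
    to_sbml,
    write_sbml,
)
from pbpksim.simulate import simulate


def _root(bundle):
    return etree.fromstring(bundle.document.encode())


def _model_el(bundle):
    return _root(bundle).find(f"{{{SBML_NS}}}model")


class TestExportStructure:
    def test_reference_document_counts(self, man_model, scenario):
        bundle = to_sbml(man_model, scenario)
        mdl = _model_el(bundle)
        comps = mdl.findall(f"{{{SBML_NS}}}listOfCompartments/{{{SBML_NS}}}compartment")
        species = mdl.findall(f"{{{SBML_NS}}}listOfSpecies/{{{SBML_NS}}}species")
        events = mdl.findall(f"{{{SBML_NS}}}listOfEvents/{{{SBML_NS}}}event")
        assert len(comps) == 3 and len(species) == 3 and len(events) == 2
        assert check_consistency(bundle) == []

    def test_every_parameter_has_units(self, man_model, scenario):
        mdl = _model_el(to_sbml(man_model, scenario))
        params = mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
        assert params and all(p.get("units") for p in params)

    def test_rate_and_assignment_rules_per_compartment(self, man_model, scenario):
        mdl = _model_el(to_sbml(man_model, scenario))
        rules = mdl.findall(f"{{{SBML_NS}}}listOfRules/*")
        kinds = {}
        for r in rules:
            kinds.setdefault(etree.QName(r).localname, []).append(r.get("variable"))
        assert sorted(kinds["rateRule"]) == ["A_blood", "A_liver", "A_others"]
        assert sorted(kinds["assignmentRule"]) == ["C_blood", "C_liver", "C_others"]

    def test_dosing_initial_value_follows_event_semantics(self, man_model, scenario):
        def dosing_value(s):
            mdl = _model_el(to_sbml(man_model, s))
            (p,) = [p for p in mdl.iterfind(
                f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")
                if p.get("id") == "Dosing"]
            return float(p.get("value"))

        assert dosing_value(scenario) == 100.0  # exposure starts at t0
        delayed = dataclasses.replace(scenario, Time_start_expos=10.0)
        assert dosing_value(delayed) == 0.0

    def test_metadata_round_trips_via_annotation(self, man_model, scenario, complete_metadata):
        model = man_model.with_metadata(complete_metadata)
        back, _ = from_sbml(to_sbml(model, scenario))
        assert back.metadata == complete_metadata

    def test_inconsistent_model_refuses_export(self, man_model, scenario):
        tampered = dataclasses.replace(
            man_model, blood=BloodPool(V_blood=5.3, W_blood=5.3, QC=7.0))
        with pytest.raises(ValueError, match="inconsistent"):
            to_sbml(tampered, scenario)


class TestConsistencyChecker:
    def test_detects_missing_units(self, man_model, scenario):
        root = _root(to_sbml(man_model, scenario))
        mdl = root.find(f"{{{SBML_NS}}}model")
        p = mdl.findall(f"{{{SBML_NS}}}listOfParameters/{{{SBML_NS}}}parameter")[0]
        del p.attrib["units"]
        errors = check_consistency(etree.tostring(root))
        assert any("unit" in e for e in errors)

    def test_detects_duplicate_id(self, man_model, scenario):
        root = _root(to_sbml(man_model, scenario))
        mdl = root.find(f"{{{SBML_NS}}}model")
        params = mdl.find(f"{{{SBML_NS}}}listOfParameters")
        params[1].set("id", params[0].get("id"))
        errors = check_consistency(etree.tostring(root))
        assert any("duplicate" in e for e in errors)

    def test_detects_undeclared_math_symbol(self, man_model, scenario):
        root = _root(to_sbml(man_model, scenario))
        ci = root.find(f".//{{{MATHML_NS}}}ci")
        ci.text = " no_such_symbol "
        errors = check_consistency(etree.tostring(root))
        assert any("no_such_symbol" in e for e in errors)


class TestImport:
    def test_round_trip_identity(self, man_model, scenario, complete_metadata):
        model = man_model.with_metadata(complete_metadata)
        back, s_back = from_sbml(to_sbml(model, scenario))
        assert s_back == scenario
        assert back.BW == model.BW
        assert back.blood == model.blood
        assert back.tissues == model.tissues
        assert back.initial_amounts == model.initial_amounts
        assert back.compartment_names == model.compartment_names

    def test_reaction_document_rejected_naming_element(self, man_model, scenario):
        root = _root(to_sbml(man_model, scenario))
        mdl = root.find(f"{{{SBML_NS}}}model")
        lor = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
        etree.SubElement(lor, f"{{{SBML_NS}}}reaction", id="r1")
        with pytest.raises(UnsupportedModelError, match="reaction"):
            from_sbml(etree.tostring(root))

    def test_missing_rate_rule_rejected(self, man_model, scenario):
        root = _root(to_sbml(man_model, scenario))
        mdl = root.find(f"{{{SBML_NS}}}model")
        rules = mdl.find(f"{{{SBML_NS}}}listOfRules")
        (rr,) = [r for r in rules if r.get("variable") == "A_liver"]
        rules.remove(rr)
        with pytest.raises(UnsupportedModelError, match="A_liver"):
            from_sbml(etree.tostring(root))

    def test_file_round_trip(self, man_model, scenario, tmp_path):
        path = tmp_path / "model.xml"
        write_sbml(man_model, scenario, path)
        back, s_back = read_sbml(path)
        assert back.tissues == man_model.tissues and s_back == scenario


class TestSimulationParity:
    def test_round_trip_trajectories_match(self, man_model, scenario):
        back, s_back = from_sbml(to_sbml(man_model, scenario))
        r1 = simulate(man_model, scenario)
        r2 = simulate(back, s_back)
        scale = max(float(np.max(np.abs(r1.amounts))), 1.0)
        assert np.max(np.abs(r1.amounts - r2.amounts)) / scale <= 1e-6


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    n_tissues=st.integers(1, 4),
    data=st.data(),
)
def test_property_round_trip_random_models(n_tissues, data):
    """Round-trip identity on parameters and initial values for randomized
    consistent models."""
    pos = st.floats(0.1, 50.0, allow_nan=False)
    weights = data.draw(st.lists(pos, min_size=n_tissues, max_size=n_tissues))
    flows = data.draw(st.lists(pos, min_size=n_tissues, max_size=n_tissues))
    pcs = data.draw(st.lists(st.floats(0.2, 10.0), min_size=n_tissues, max_size=n_tissues))
    ers = data.draw(st.lists(st.floats(0.0, 1.0), min_size=n_tissues, max_size=n_tissues))
    inits = data.draw(st.lists(st.floats(0.0, 100.0),
                               min_size=n_tissues + 1, max_size=n_tissues + 1))
    V_blood = data.draw(pos)
    tissues = tuple(
        Tissue(f"tissue{i}", W=weights[i], Q=flows[i], PC=pcs[i], ER=ers[i])
        for i in range(n_tissues)
    )
    model = PBPKModel(
        BW=V_blood + sum(weights),
        blood=BloodPool(V_blood=V_blood, W_blood=V_blood, QC=sum(flows)),
        tissues=tissues,
        initial_amounts=tuple(inits),
        metadata=ModelMetadata(model_name="random"),
        closure_rtol=1e-9,
        name="random",
    )
    scenario = ExposureScenario(Dose=data.draw(st.floats(0, 500)),
                                Time_start_simul=0.0, Time_end_simul=400.0,
                                Time_start_expos=data.draw(st.floats(0, 100)),
                                Time_end_expos=data.draw(st.floats(100, 400)))
    bundle = to_sbml(model, scenario)
    assert check_consistency(bundle) == []
    back, s_back = from_sbml(bundle)
    assert back.tissues == model.tissues
    assert back.blood == model.blood
    assert back.initial_amounts == model.initial_amounts
    assert s_back == scenario
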