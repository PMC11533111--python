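"""Core model types, dosing, concentrations, right-hand side and
validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbpksim.model import (
    BloodPool,
    ExposureScenario,
    PBPKModel,
    Tissue,
    amounts_from_concentrations,
    clearance_rate,
    concentrations,
    dosing_rate,
    rhs,
    validate_model,
)
from pbpksim.physiology import build_reference_model, default_scenario


class TestInvariants:
    def test_tissue_rejects_nonpositive_and_out_of_range(self):
        with pytest.raises(ValueError):
            Tissue("liver", W=0.0, Q=1.0, PC=1.0)
        with pytest.raises(ValueError):
            Tissue("liver", W=1.0, Q=-1.0, PC=1.0)
        with pytest.raises(ValueError):
            Tissue("liver", W=1.0, Q=1.0, PC=1.0, ER=1.5)

    def test_scenario_rejects_disordered_times(self):
        with pytest.raises(ValueError):
            ExposureScenario(Dose=1, Time_start_simul=0, Time_end_simul=100,
                             Time_start_expos=50, Time_end_expos=200)

    def test_model_rejects_duplicate_names_and_negative_amounts(self):
        blood = BloodPool(V_blood=5.0, W_blood=5.0, QC=6.0)
        tissues = (Tissue("liver", 2.0, 3.0, 1.5), Tissue("liver", 2.0, 3.0, 1.5))
        with pytest.raises(ValueError, match="unique"):
            PBPKModel(BW=9.0, blood=blood, tissues=tissues)
        with pytest.raises(ValueError, match=">= 0"):
            PBPKModel(BW=12.0, blood=blood,
                      tissues=(Tissue("liver", 7.0, 6.0, 1.5),),
                      initial_amounts=(-1.0, 0.0))


class TestDosingRate:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (100.0, 100.0),   # mid-infusion
            (300.0, 0.0),     # depuration
            (200.0, 100.0),   # closed upper boundary
            (0.0, 100.0),     # closed lower boundary
            (-1.0, 0.0),      # before exposure
        ],
    )
    def test_window(self, scenario, t, expected):
        assert dosing_rate(t, scenario) == expected

    def test_nonfinite_time_rejected(self, scenario):
        with pytest.raises(ValueError):
            dosing_rate(float("nan"), scenario)


class TestConcentrations:
    def test_identity_ratio_and_zero(self, man_model):
        c = concentrations([5.3, 0.0, 0.0], man_model)
        assert c[0] == pytest.approx(1.0)  # 5.3 mg / 5.3 L
        assert np.all(concentrations([0.0, 0.0, 0.0], man_model) == 0.0)

    def test_tissue_ratio(self, man_model):
        # A_liver / W_liver with W_liver = 0.026 * 73 = 1.898 kg
        c = concentrations([0.0, 3.796, 0.0], man_model)
        assert c[1] == pytest.approx(2.0)

    def test_roundtrip_with_amounts(self, man_model):
        state = np.array([1.2, 3.4, 5.6])
        back = amounts_from_concentrations(concentrations(state, man_model), man_model)
        np.testing.assert_allclose(back, state, rtol=1e-14)

    def test_dimension_mismatch(self, man_model):
        with pytest.raises(ValueError):
            concentrations([1.0, 2.0], man_model)


class TestRhs:
    def test_zero_state_during_infusion_is_pure_dosing(self, man_model, scenario):
        d = rhs(100.0, [0.0, 0.0, 0.0], man_model, scenario)
        np.testing.assert_allclose(d, [100.0, 0.0, 0.0])

    def test_steady_state_annihilates_rhs(self, man_model, scenario):
        from pbpksim.simulate import steady_state_infusion

        ss = steady_state_infusion(man_model, scenario.Dose)
        conc = np.array([ss[n] for n in man_model.compartment_names])
        state = amounts_from_concentrations(conc, man_model)
        d = rhs(100.0, state, man_model, scenario)  # during infusion
        assert np.max(np.abs(d)) < 1e-9

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e4), min_size=3, max_size=3),
           st.floats(-100, 500))
    def test_mass_balance_identity(self, amounts, t):
        """Sum of net flows equals dosing minus clearance for any state:
        inter-compartment transfer terms cancel pairwise."""
        model = build_reference_model("man")
        scenario = default_scenario()
        d = rhs(t, amounts, model, scenario)
        expected = dosing_rate(t, scenario) - clearance_rate(amounts, model)
        assert d.sum() == pytest.approx(expected, rel=1e-12, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e3), min_size=3, max_size=3),
           st.lists(st.floats(0, 1e3), min_size=3, max_size=3))
    def test_linearity_in_state(self, s1, s2):
        """rhs(t, s) - rhs(t, 0) is linear in s (dosing is the only affine
        term)."""
        model = build_reference_model("man")
        scenario = default_scenario()
        t = 50.0
        f = lambda s: rhs(t, s, model, scenario)
        base = f([0.0, 0.0, 0.0])
        lhs = f(np.add(s1, s2)) - base
        parts = (f(s1) - base) + (f(s2) - base)
        np.testing.assert_allclose(lhs, parts, rtol=1e-9, atol=1e-9)


class TestClearance:
    def test_zero_blood_concentration(self, man_model):
        assert clearance_rate([0.0, 5.0, 5.0], man_model) == 0.0

    def test_reference_clearance_matches_dose_at_steady_state(self, man_model):
        # C_blood_ss = Dose / (Q_liver_total * ER_liver); clearance there
        # must equal the infusion rate
        c_ss = 100.0 / (1.6575 * 0.7)
        state = [c_ss * man_model.blood.V_blood, 0.0, 0.0]
        assert clearance_rate(state, man_model) == pytest.approx(100.0, rel=1e-9)

    def test_no_extraction_no_clearance(self, model_factory):
        model = model_factory(ER=(0.0, 0.0))
        assert clearance_rate([10.0, 5.0, 2.0], model) == 0.0


class TestValidateModel:
    def test_reference_models_pass(self, man_model, woman_model):
        assert validate_model(man_model) == []
        assert validate_model(woman_model) == []

    def test_flow_closure_finding(self, man_model):
        import dataclasses

        bad_blood = BloodPool(V_blood=5.3, W_blood=5.3, QC=7.0)
        tampered = dataclasses.replace(man_model, blood=bad_blood)
        findings = validate_model(tampered)
        assert [f.code for f in findings] == ["flow_closure"]
        assert findings[0].value == pytest.approx(abs(6.5 - 7.0) / 7.0, rel=1e-6)

    def test_weight_closure_finding(self, man_model):
        import dataclasses

        tampered = dataclasses.replace(man_model, BW=80.0)
        assert [f.code for f in validate_model(tampered)] == ["weight_closure"]

    def test_range_finding_via_bypassed_constructor(self, man_model):
        # bypass the dataclass guard to emulate a deserialised bad model
        bad = object.__new__(Tissue)
        object.__setattr__(bad, "name", "liver")
        object.__setattr__(bad, "W", 1.898)
        object.__setattr__(bad, "Q", 1.6575)
        object.__setattr__(bad, "PC", 1.5)
        object.__setattr__(bad, "ER", 1.5)
        import dataclasses

        tampered = dataclasses.replace(man_model, tissues=(bad, man_model.tissues[1]))
        assert any(f.code == "range" for f in validate_model(tampered))
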