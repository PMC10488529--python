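import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vet_era.effects import EcotoxEndpoint, NoEndpointError, derive_pnecs
from vet_era.exposure import (
    ProductScenario,
    Regimen,
    SubstanceProperties,
    build_pec_matrix,
)
from vet_era.guideline_data import DEFAULT_SOIL, HusbandryDefaults
from vet_era.risk_engine import (
    RefinementInputs,
    phase1_trigger,
    refine_pec,
    risk_quotient,
    run_assessment,
)
from vet_era.units import Conc, UnitError


class TestPhase1Trigger:
    def test_worked_example_triggers(self):
        assert phase1_trigger(868.88) is True

    def test_boundary_is_strict(self):
        assert phase1_trigger(100.0) is False

    def test_below(self):
        assert phase1_trigger(99.9) is False

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phase1_trigger(-0.1)


class TestRiskQuotient:
    def test_soil_printed_pair(self):
        assert risk_quotient(Conc(0.868, "mg/kg"), Conc(7.69, "mg/kg")) == pytest.approx(
            0.113, abs=5e-4
        )

    def test_sediment_printed_pair(self):
        assert risk_quotient(Conc(1.721, "mg/kg"), Conc(9.93, "mg/kg")) == pytest.approx(
            0.173, abs=5e-4
        )

    def test_cross_unit_normalization(self):
        assert risk_quotient(Conc(37.66, "µg/L"), Conc(1.0, "mg/L")) == pytest.approx(
            0.03766
        )

    def test_nonpositive_pnec_rejected(self):
        with pytest.raises(ValueError):
            risk_quotient(Conc(1.0, "mg/L"), Conc(0.0, "mg/L"))

    def test_incompatible_bases_rejected(self):
        with pytest.raises(UnitError):
            risk_quotient(Conc(1.0, "mg/L"), Conc(1.0, "mg/kg"))

    @given(
        pec=st.floats(min_value=1e-6, max_value=1e6),
        pnec=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_unit_invariance(self, pec, pnec):
        r1 = risk_quotient(Conc(pec, "mg/L"), Conc(pnec, "mg/L"))
        r2 = risk_quotient(Conc(pec * 1000, "µg/L"), Conc(pnec, "mg/L"))
        r3 = risk_quotient(Conc(pec, "mg/L"), Conc(pnec * 1000, "µg/L"))
        assert r2 == pytest.approx(r1, rel=1e-12)
        assert r3 == pytest.approx(r1, rel=1e-12)


class TestRefinePec:
    def test_identity(self):
        assert refine_pec(868.88, RefinementInputs()) == 868.88

    def test_linearity(self):
        assert refine_pec(10.0, RefinementInputs(0.5, 1, 1)) == pytest.approx(5.0)

    def test_combined_fractions(self):
        got = refine_pec(868.88, RefinementInputs(0.6, 0.5, 0.5))
        assert got == pytest.approx(130.332)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_fraction_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            RefinementInputs(fraction_excreted=bad)


class TestRunAssessment:
    def test_worked_example(self, scenario, substance_overridden, endpoints, soil):
        result = run_assessment(scenario, substance_overridden, endpoints, soil=soil)
        assert result.conclusion == "acceptable_R_lt_1"
        assert result.worst_case_species == "piglet"
        assert all(result.phase1_triggered.values())
        r = result.headline
        assert r["groundwater"] == pytest.approx(0.028, abs=5e-4)
        assert r["surfacewater"] == pytest.approx(0.0377, abs=5e-4)
        assert r["soil"] == pytest.approx(0.113, abs=5e-4)
        assert r["sediment"] == pytest.approx(0.173, abs=1e-3)

    def test_dose_scaled_down_stops_in_phase1(self, substance, endpoints, soil):
        sc = ProductScenario(
            "p", 250.0,
            (Regimen("piglet", 0.25, 4), Regimen("chicken", 0.10, 4)),
        )
        result = run_assessment(sc, substance, endpoints, soil=soil)
        assert result.conclusion == "phase1_stop"
        assert not any(result.phase1_triggered.values())
        assert not result.headline  # no Phase II quantities computed

    def test_low_pnec_routes_to_refine_pec(self, scenario, substance, soil):
        endpoints = [EcotoxEndpoint("water", "algae", "NOEC", 0.1, 10)]  # 0.01 mg/L
        result = run_assessment(scenario, substance, endpoints, soil=soil)
        assert result.headline["surfacewater"] > 1
        assert result.conclusion == "refine_pec"

    def test_refinement_can_resolve_risk(self, scenario, substance, soil):
        endpoints = [EcotoxEndpoint("water", "algae", "NOEC", 0.5, 10)]  # 0.05 mg/L
        crude = run_assessment(scenario, substance, endpoints, soil=soil)
        assert crude.conclusion == "refine_pec"
        refined = run_assessment(
            scenario, substance, endpoints, soil=soil,
            refinement=RefinementInputs(0.3, 0.5, 0.5),
        )
        assert refined.conclusion == "acceptable_R_lt_1"
        assert refined.refined_headline["surfacewater"] == pytest.approx(
            crude.headline["surfacewater"] * 0.075, rel=1e-12
        )

    def test_persistent_risk_marks_refine_pnec(self, scenario, substance, soil):
        endpoints = [EcotoxEndpoint("water", "algae", "NOEC", 0.01, 10)]
        result = run_assessment(
            scenario, substance, endpoints, soil=soil,
            refinement=RefinementInputs(0.9, 0.9, 0.9),
        )
        assert result.conclusion == "refine_pnec"

    def test_missing_water_endpoint_names_compartment(self, scenario, substance, soil):
        endpoints = [EcotoxEndpoint("soil", "earthworm", "NOEC", 2000.0, 100)]
        with pytest.raises(NoEndpointError, match="water"):
            run_assessment(scenario, substance, endpoints, soil=soil)

    def test_trace_contains_every_headline_number(
        self, scenario, substance_overridden, endpoints, soil
    ):
        result = run_assessment(scenario, substance_overridden, endpoints, soil=soil)
        traced = [rec.value for rec in result.trace]
        for conc in result.pec.headline.values():
            assert any(v == pytest.approx(conc.value, rel=1e-12) for v in traced)
        for res in result.pnec.values():
            assert any(v == pytest.approx(res.selected, rel=1e-12) for v in traced)
        for r in result.headline.values():
            assert any(v == pytest.approx(r, rel=1e-12) for v in traced)
        symbols = {rec.symbol for rec in result.trace}
        assert {"PECsol initial", "PECsoil20cm", "PNECwater", "Rsoil", "conclusion"} <= symbols

    def test_trace_nonempty_even_on_phase1_stop(self, substance, endpoints, soil):
        sc = ProductScenario("p", 250.0, (Regimen("piglet", 0.01, 1),))
        result = run_assessment(sc, substance, endpoints, soil=soil)
        assert result.trace

    def test_conclusion_monotone_in_pnec(self, scenario, substance, soil):
        order = {"phase1_stop": 0, "acceptable_R_lt_1": 1, "refine_pec": 2, "refine_pnec": 3}
        previous = None
        for noec in (0.05, 0.5, 5.0, 50.0):
            endpoints = [EcotoxEndpoint("water", "algae", "NOEC", noec, 10)]
            concl = run_assessment(scenario, substance, endpoints, soil=soil).conclusion
            if previous is not None:
                assert order[concl] <= order[previous]
            previous = concl

    def test_conclusion_monotone_in_dose(self, substance, endpoints, soil):
        order = {"phase1_stop": 0, "acceptable_R_lt_1": 1, "refine_pec": 2, "refine_pnec": 3}
        previous = None
        for dose in (0.1, 25.0, 2500.0):
            sc = ProductScenario("p", 250.0, (Regimen("piglet", dose, 4),))
            concl = run_assessment(sc, substance, endpoints, soil=soil).conclusion
            if previous is not None:
                assert order[concl] >= order[previous]
            previous = concl


@st.composite
def random_scenarios(draw):
    n_species = draw(st.integers(min_value=1, max_value=4))
    regimens = []
    registry = {}
    for i in range(n_species):
        sp = f"species_{i}"
        regimens.append(
            Regimen(
                sp,
                draw(st.floats(min_value=0.0, max_value=200.0)),
                draw(st.integers(min_value=1, max_value=10)),
            )
        )
        registry[sp] = HusbandryDefaults(
            sp,
            draw(st.floats(min_value=0.5, max_value=100.0)),
            draw(st.floats(min_value=0.1, max_value=1.0)),
        )
    substance = SubstanceProperties(
        "x", 300.0, 100.0, 1.0,
        koc=draw(st.floats(min_value=0.0, max_value=5000.0)),
    )
    endpoints = [
        EcotoxEndpoint(
            "water", "algae", "NOEC",
            draw(st.floats(min_value=0.01, max_value=100.0)),
            draw(st.integers(min_value=1, max_value=1000)),
        ),
        EcotoxEndpoint(
            "soil", "earthworm", "NOEC",
            draw(st.floats(min_value=0.1, max_value=5000.0)),
            draw(st.integers(min_value=1, max_value=1000)),
        ),
    ]
    scenario = ProductScenario("random product", 100.0, tuple(regimens))
    return scenario, substance, endpoints, registry


@settings(max_examples=100, deadline=None)
@given(data=random_scenarios())
def test_oracle_equivalence_on_random_scenarios(data):
    """run_assessment == hand-composition of the scalar ops, 100 scenarios."""
    scenario, substance, endpoints, registry = data
    result = run_assessment(scenario, substance, endpoints, registry=registry)

    # hand-composed oracle
    from vet_era.exposure import (
        partition_factor,
        pec_groundwater,
        pec_sediment,
        pec_soil_at_depth,
        pec_soil_initial,
        pec_surfacewater,
    )

    soil = DEFAULT_SOIL
    soil_pecs = {
        r.species: pec_soil_initial(r, registry[r.species], soil)
        for r in scenario.regimens
    }
    expected_trigger = {sp: v > 100.0 for sp, v in soil_pecs.items()}
    assert result.phase1_triggered == expected_trigger
    if not any(expected_trigger.values()):
        assert result.conclusion == "phase1_stop"
        return

    worst = max(soil_pecs, key=lambda sp: soil_pecs[sp])
    assert result.worst_case_species == worst
    f = partition_factor(substance)
    p_soil = soil_pecs[worst]
    p_sw = pec_surfacewater(p_soil, f, soil)
    pnecs = derive_pnecs(endpoints, substance)
    expected_R = {
        "soil": (p_soil / 1000.0) / pnecs["soil"].selected,
        "groundwater": (pec_groundwater(pec_soil_at_depth(p_soil, soil), f) / 1000.0)
        / pnecs["water"].selected,
        "surfacewater": (p_sw / 1000.0) / pnecs["water"].selected,
        "sediment": (pec_sediment(p_sw, substance) / 1000.0) / pnecs["sediment"].selected,
    }
    for comp, expected in expected_R.items():
        assert result.headline[comp] == pytest.approx(expected, rel=1e-9)
    if all(v < 1 for v in expected_R.values()):
        assert result.conclusion == "acceptable_R_lt_1"
    else:
        assert result.conclusion == "refine_pec"
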