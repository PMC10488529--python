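"""Decision tree: Phase I trigger, risk quotients and stop/refine logic.

Phase I stops the assessment when no species' soil PEC exceeds the
100 µg/kg trigger.  Otherwise Phase II Tier A computes compartment PECs
from the worst-case species, derives PNECs, and forms risk quotients
R = PEC/PNEC.  All R < 1 means the risk is acceptable and the assessment
ends; any R >= 1 sends the scenario down the refinement branch (reduced
excretion and degradation fractions), and a refined R still >= 1 marks the
effect side for refinement.  Every intermediate quantity is recorded in an
ordered decision trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from vet_era.effects import EcotoxEndpoint, PnecResult, derive_pnecs
from vet_era.exposure import (
    COMPARTMENTS,
    PecMatrix,
    ProductScenario,
    SubstanceProperties,
    build_pec_matrix,
)
from vet_era.guideline_data import SoilScenario
from vet_era.units import Conc, UnitError, convert

#: Phase I soil trigger (µg/kg); assessment proceeds to Phase II strictly above it.
PHASE1_TRIGGER_UG_PER_KG = 100.0

#: Risk compartment -> PNEC compartment (both waters share the aquatic PNEC).
_PNEC_FOR = {
    "soil": "soil",
    "groundwater": "water",
    "surfacewater": "water",
    "sediment": "sediment",
}

CONCLUSIONS = ("phase1_stop", "acceptable_R_lt_1", "refine_pec", "refine_pnec")


@dataclass(frozen=True)
class RefinementInputs:
    """Exposure refinement fractions, each in (0, 1]; identity by default."""

    fraction_excreted: float = 1.0
    fraction_remaining_after_manure_degradation: float = 1.0
    fraction_remaining_after_soil_degradation: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "fraction_excreted",
            "fraction_remaining_after_manure_degradation",
            "fraction_remaining_after_soil_degradation",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @property
    def product(self) -> float:
        return (
            self.fraction_excreted
            * self.fraction_remaining_after_manure_degradation
            * self.fraction_remaining_after_soil_degradation
        )


@dataclass(frozen=True)
class TraceRecord:
    """One evaluated quantity of the decision tree."""

    symbol: str  # e.g. "PECsol initial", "PNECwater", "Rsoil"
    species: Optional[str]
    value: float
    unit: str
    formula: str


@dataclass
class RiskMatrix:
    """Risk quotients per (species, compartment) plus the headline run."""

    entries: dict[tuple[str, str], float] = field(default_factory=dict)
    headline: dict[str, float] = field(default_factory=dict)
    headline_pairs: dict[str, tuple[Conc, Conc]] = field(default_factory=dict)
    phase1_triggered: dict[str, bool] = field(default_factory=dict)
    conclusion: str = ""
    worst_case_species: str = ""
    pec: Optional[PecMatrix] = None
    pnec: dict[str, PnecResult] = field(default_factory=dict)
    refined_headline: dict[str, float] = field(default_factory=dict)
    trace: list[TraceRecord] = field(default_factory=list)

    @property
    def max_risk(self) -> float:
        return max(self.headline.values(), default=0.0)


def phase1_trigger(pec_soil: float) -> bool:
    """True iff the Phase I soil PEC exceeds 100 µg/kg (strictly)."""
    if pec_soil < 0:
        raise ValueError("pec_soil must be non-negative")
    return pec_soil > PHASE1_TRIGGER_UG_PER_KG


def risk_quotient(pec: Conc, pnec: Conc) -> float:
    """Dimensionless R = PEC/PNEC after unit normalization.

    Both concentrations must share a base (per-litre or per-kilogram);
    crossing bases has no physical meaning and raises :class:`UnitError`.
    """
    if pnec.value <= 0:
        raise ValueError("PNEC must be strictly positive")
    pec_norm = convert(pec.value, pec.unit, pnec.unit)
    return pec_norm / pnec.value


def refine_pec(pec: float, refinement: RefinementInputs) -> float:
    """Refined PEC: the crude value scaled by the exposure fractions."""
    if pec < 0:
        raise ValueError("pec must be non-negative")
    return pec * refinement.product


def run_assessment(
    scenario: ProductScenario,
    substance: SubstanceProperties,
    endpoints: list[EcotoxEndpoint],
    registry=None,
    soil: SoilScenario | None = None,
    refinement: RefinementInputs | None = None,
    sediment_af_from_water: bool = False,
) -> RiskMatrix:
    """Execute the full decision tree for a product scenario.

    Returns a :class:`RiskMatrix` whose ``conclusion`` is one of
    ``phase1_stop`` (no species triggers Phase II), ``acceptable_R_lt_1``,
    ``refine_pec`` (some crude R >= 1, exposure refinement indicated) or
    ``refine_pnec`` (refined R still >= 1, effect data need refinement).
    """
    soil = soil if soil is not None else SoilScenario()
    result = RiskMatrix()
    trace = result.trace

    pec = build_pec_matrix(scenario, substance, registry=registry, soil=soil)
    result.pec = pec
    result.worst_case_species = pec.worst_case_species

    for regimen in scenario.regimens:
        sp = regimen.species
        p_soil = pec.value(sp, "soil").value
        trace.append(
            TraceRecord(
                "PECsol initial", sp, p_soil, "µg/kg",
                "D*Ad*Fh*H*lrN*1000/(rho_b*A*d)",
            )
        )
        result.phase1_triggered[sp] = phase1_trigger(p_soil)
        trace.append(
            TraceRecord(
                "Phase I trigger", sp, float(result.phase1_triggered[sp]), "",
                f"PECsol initial > {PHASE1_TRIGGER_UG_PER_KG} µg/kg",
            )
        )

    if not any(result.phase1_triggered.values()):
        result.conclusion = "phase1_stop"
        trace.append(
            TraceRecord(
                "conclusion", None, 0.0, "",
                "no species exceeds the Phase I soil trigger; assessment stops",
            )
        )
        return result

    worst = pec.worst_case_species
    trace.append(
        TraceRecord(
            "worst case species", worst, pec.value(worst, "soil").value, "µg/kg",
            "argmax over species of PECsol initial",
        )
    )
    inter = pec.intermediates[worst]
    trace.append(
        TraceRecord("PECsoil20cm", worst, inter["PECsoil_deep"], "µg/kg",
                    "PECsol initial * d_phase1/d_deep")
    )
    for compartment in COMPARTMENTS:
        c = pec.headline[compartment]
        trace.append(
            TraceRecord(f"PEC{compartment}", worst, c.value, c.unit, "Tier A chain")
        )

    pnecs = derive_pnecs(endpoints, substance, sediment_af_from_water)
    result.pnec = pnecs
    for comp, res in pnecs.items():
        if res.af_value is not None:
            trace.append(
                TraceRecord(f"PNEC{comp}FA", None, res.af_value, res.unit,
                            "min over endpoints of value/AF")
            )
        if res.ep_value is not None:
            trace.append(
                TraceRecord(f"PNEC{comp}EP", None, res.ep_value, res.unit,
                            "partition factor * PNECwater")
            )
        trace.append(
            TraceRecord(f"PNEC{comp}", None, res.selected, res.unit,
                        f"selected by {res.method_used}")
        )

    refinement = refinement if refinement is not None else RefinementInputs()

    def quotients(scale: float) -> dict[str, float]:
        out: dict[str, float] = {}
        for compartment in COMPARTMENTS:
            pec_c = pec.headline[compartment]
            pnec_res = pnecs[_PNEC_FOR[compartment]]
            pnec_c = Conc(pnec_res.selected, pnec_res.unit)
            out[compartment] = risk_quotient(
                Conc(pec_c.value * scale, pec_c.unit), pnec_c
            )
        return out

    result.headline = quotients(1.0)
    for compartment, r in result.headline.items():
        pec_c = pec.headline[compartment]
        pnec_res = pnecs[_PNEC_FOR[compartment]]
        result.headline_pairs[compartment] = (pec_c, Conc(pnec_res.selected, pnec_res.unit))
        trace.append(
            TraceRecord(f"R{compartment}", worst, r, "", "PEC/PNEC (unit-normalized)")
        )

    # per-species matrix view of R
    for regimen in scenario.regimens:
        sp = regimen.species
        for compartment in COMPARTMENTS:
            pec_c = pec.value(sp, compartment)
            pnec_res = pnecs[_PNEC_FOR[compartment]]
            result.entries[(sp, compartment)] = risk_quotient(
                pec_c, Conc(pnec_res.selected, pnec_res.unit)
            )

    if all(r < 1 for r in result.headline.values()):
        result.conclusion = "acceptable_R_lt_1"
        trace.append(
            TraceRecord("conclusion", None, result.max_risk, "",
                        "all R < 1: acceptable, assessment ends")
        )
        return result

    # refinement branch: some crude R >= 1
    if refinement.product == 1.0:
        # no refinement data supplied; exposure refinement is the next step
        result.conclusion = "refine_pec"
        trace.append(
            TraceRecord("conclusion", None, result.max_risk, "",
                        "some R >= 1: refine PEC (excretion/degradation data needed)")
        )
        return result

    result.refined_headline = quotients(refinement.product)
    for compartment, r in result.refined_headline.items():
        trace.append(
            TraceRecord(f"R{compartment} refined", worst, r, "",
                        "PEC * excretion/degradation fractions / PNEC")
        )
    if all(r < 1 for r in result.refined_headline.values()):
        result.conclusion = "acceptable_R_lt_1"
        trace.append(
            TraceRecord("conclusion", None, max(result.refined_headline.values()), "",
                        "refined R < 1: acceptable, assessment ends")
        )
    else:
        result.conclusion = "refine_pnec"
        trace.append(
            TraceRecord("conclusion", None, max(result.refined_headline.values()), "",
                        "refined R still >= 1: effect-side refinement required")
        )
    return result
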