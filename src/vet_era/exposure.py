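"""Predicted environmental concentrations (PEC).

Phase I computes the soil concentration after one year of manure spreading
under the total-residue approach (the whole administered dose is assumed
excreted unchanged).  Phase II Tier A derives water and sediment
concentrations from the worst-case soil PEC by linear equilibrium
partitioning on the organic-carbon coefficient Koc.

Units are fixed per compartment: µg/kg dry weight for soil and sediment,
µg/L for groundwater and surface water.  Rounding happens only at report
rendering, never inside these functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from vet_era.guideline_data import HusbandryDefaults, SoilScenario, get_defaults
from vet_era.units import Conc

COMPARTMENTS = ("soil", "groundwater", "surfacewater", "sediment")

#: Unit attached to each compartment's PEC.
COMPARTMENT_UNITS = {
    "soil": "µg/kg",
    "groundwater": "µg/L",
    "surfacewater": "µg/L",
    "sediment": "µg/kg",
}

# linear soil--water partition model coefficients (L/kg per unit Koc)
_SOIL_WATER_INTERCEPT = 0.1176
_SOIL_WATER_SLOPE = 0.01764
# suspended-matter (sediment--water) coefficients
_SED_WATER_INTERCEPT = 0.783
_SED_WATER_SLOPE = 0.0217


@dataclass(frozen=True)
class Regimen:
    """One species' dosing regimen of the product."""

    species: str
    dose_D: float  # mg active ingredient / kg body weight / day
    duration_Ad: int  # consecutive treatment days

    def __post_init__(self) -> None:
        if self.dose_D < 0:
            raise ValueError("dose_D must be non-negative")
        if int(self.duration_Ad) != self.duration_Ad or self.duration_Ad < 1:
            raise ValueError("duration_Ad must be an integer >= 1")


@dataclass(frozen=True)
class ProductScenario:
    """The veterinary product and its per-species dosing regimens."""

    name: str
    ai_content: float  # active ingredient mass fraction, mg/g
    regimens: tuple[Regimen, ...]
    route: str = "oral, drinking water"

    def __post_init__(self) -> None:
        if not self.regimens:
            raise ValueError("a scenario needs at least one regimen")
        if self.ai_content <= 0:
            raise ValueError("ai_content must be strictly positive")
        species = [r.species for r in self.regimens]
        if len(set(species)) != len(species):
            raise ValueError("duplicate species in regimens")


@dataclass(frozen=True)
class SubstanceProperties:
    """Physico-chemical parameters of the active ingredient.

    ``molar_mass_MW``, ``solubility_SOL`` and ``vapor_pressure_VP`` are
    stored and reported as substance metadata; the Tier A chain implemented
    here depends only on ``koc``.  ``partition_factor_override`` replaces
    the linear soil--water partition factor verbatim when set;
    ``sediment_pec_override`` (µg/kg) replaces the suspended-matter sediment
    estimate when set.
    """

    name: str
    molar_mass_MW: float
    solubility_SOL: float  # mg/L
    vapor_pressure_VP: float  # as stated by the data source
    koc: float  # L/kg
    partition_factor_override: float | None = None
    sediment_pec_override: float | None = None

    def __post_init__(self) -> None:
        if self.koc < 0:
            raise ValueError("koc must be non-negative")
        if self.partition_factor_override is not None and self.partition_factor_override <= 0:
            raise ValueError("partition_factor_override must be strictly positive")


def pec_soil_initial(
    regimen: Regimen, defaults: HusbandryDefaults, soil: SoilScenario
) -> float:
    """Phase I total-residue soil concentration (µg/kg dry weight).

    PECsoil = D * Ad * Fh * H * lrN * 1000 / (rho_b * A * d)

    with D the daily dose (mg/kg bw), Ad treatment days, Fh the herd
    fraction treated, H the composite husbandry factor and lrN the areal
    nitrogen ceiling.  Linear in each of D, Ad, Fh, H.
    """
    numerator = (
        regimen.dose_D
        * regimen.duration_Ad
        * defaults.fraction_treated_Fh
        * defaults.composite_factor_H
        * soil.nitrogen_limit
        * 1000.0  # mg -> µg
    )
    soil_mass = soil.bulk_density * soil.hectare_area * soil.mixing_depth_phase1
    return numerator / soil_mass


def pec_soil_at_depth(pec_soil: float, soil: SoilScenario) -> float:
    """Soil PEC re-expressed over the deeper mixing layer (µg/kg).

    Same residue mass diluted from the Phase I incorporation depth into
    the deeper layer: PEC * d_phase1 / d_deep.
    """
    if pec_soil < 0:
        raise ValueError("pec_soil must be non-negative")
    return pec_soil * soil.mixing_depth_phase1 / soil.mixing_depth_deep


def partition_factor(substance: SubstanceProperties) -> float:
    """Soil--pore-water partition factor f (L/kg).

    Default is the linear organic-carbon model
    f = 0.1176 + 0.01764 * Koc, strictly increasing in Koc.  A stored
    override is returned verbatim when present.
    """
    if substance.partition_factor_override is not None:
        return substance.partition_factor_override
    return _SOIL_WATER_INTERCEPT + _SOIL_WATER_SLOPE * substance.koc


def pec_groundwater(pec_soil_deep: float, f: float) -> float:
    """Groundwater PEC (µg/L) as pore water of the deep soil layer."""
    if f <= 0:
        raise ValueError("partition factor must be strictly positive")
    return pec_soil_deep / f


def pec_surfacewater(pec_soil: float, f: float, soil: SoilScenario) -> float:
    """Surface-water PEC (µg/L).

    Pore water of the Phase I (shallow) soil layer, then diluted by the
    default surface-water dilution factor.
    """
    if f <= 0:
        raise ValueError("partition factor must be strictly positive")
    return pec_soil / f / soil.surface_water_dilution


def pec_sediment(pec_sw: float, substance: SubstanceProperties) -> float:
    """Sediment PEC (µg/kg).

    Default mode applies the suspended-matter partition factor
    (0.783 + 0.0217 * Koc) to the surface-water PEC.  When the substance
    carries a stored sediment override it is returned verbatim.
    """
    if pec_sw < 0:
        raise ValueError("pec_sw must be non-negative")
    if substance.sediment_pec_override is not None:
        return substance.sediment_pec_override
    return pec_sw * (_SED_WATER_INTERCEPT + _SED_WATER_SLOPE * substance.koc)


@dataclass
class PecMatrix:
    """Species x compartment PEC table plus the worst-case Tier A chain.

    ``entries`` holds the per-species matrix view; ``headline`` the
    compartment PECs derived from the worst-case species' soil PEC, which
    feed the risk quotients.  ``intermediates`` records the deep-layer soil
    and pore-water concentrations per species.
    """

    entries: dict[tuple[str, str], Conc] = field(default_factory=dict)
    headline: dict[str, Conc] = field(default_factory=dict)
    worst_case_species: str = ""
    intermediates: dict[str, dict[str, float]] = field(default_factory=dict)

    def value(self, species: str, compartment: str) -> Conc:
        return self.entries[(species, compartment)]


def build_pec_matrix(
    scenario: ProductScenario,
    substance: SubstanceProperties,
    registry=None,
    soil: SoilScenario | None = None,
) -> PecMatrix:
    """Fill all four compartments for every species in the scenario.

    Water and sediment PECs are computed per species for the matrix view
    and, for the headline chain used by risk quotients, from the
    worst-case species (highest Phase I soil PEC; ties broken by
    declaration order).
    """
    soil = soil if soil is not None else SoilScenario()
    matrix = PecMatrix()
    f = partition_factor(substance)

    soil_pecs: dict[str, float] = {}
    for regimen in scenario.regimens:
        defaults = get_defaults(regimen.species, registry)
        p_soil = pec_soil_initial(regimen, defaults, soil)
        soil_pecs[regimen.species] = p_soil
        p_deep = pec_soil_at_depth(p_soil, soil)
        p_gw = pec_groundwater(p_deep, f)
        p_sw = pec_surfacewater(p_soil, f, soil)
        p_sed = pec_sediment(p_sw, substance)
        sp = regimen.species
        matrix.entries[(sp, "soil")] = Conc(p_soil, "µg/kg")
        matrix.entries[(sp, "groundwater")] = Conc(p_gw, "µg/L")
        matrix.entries[(sp, "surfacewater")] = Conc(p_sw, "µg/L")
        matrix.entries[(sp, "sediment")] = Conc(p_sed, "µg/kg")
        matrix.intermediates[sp] = {
            "PECsoil_deep": p_deep,
            "PECporewater": p_soil / f,
        }

    # strict > keeps the first-declared species on ties
    worst = max(soil_pecs, key=lambda sp: (soil_pecs[sp], -list(soil_pecs).index(sp)))
    matrix.worst_case_species = worst
    for compartment in COMPARTMENTS:
        matrix.headline[compartment] = matrix.entries[(worst, compartment)]
    return matrix
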