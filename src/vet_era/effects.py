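"""Predicted no-effect concentrations (PNEC).

Two derivation routes are implemented.  The assessment-factor (AF) route
divides each experimental endpoint by its assessment factor and takes the
compartment minimum.  The equilibrium-partitioning (EP) route extrapolates
the water PNEC to soil and sediment through the Koc-based partition
factors.  Per compartment the lowest available candidate is selected,
except that a compartment with no experimental endpoint of its own falls
back to EP alone.
"""

from __future__ import annotations

from dataclasses import dataclass

from vet_era.exposure import (
    SubstanceProperties,
    partition_factor,
    _SED_WATER_INTERCEPT,
    _SED_WATER_SLOPE,
)

ENDPOINT_TYPES = ("NOEC", "EC50", "LC50")

#: Default assessment-factor ladder applied when a row omits AF:
#: 10 for a chronic NOEC, 100 for EC50, 1000 for an acute LC50.
DEFAULT_ASSESSMENT_FACTORS = {"NOEC": 10, "EC50": 100, "LC50": 1000}

#: Expected concentration unit per endpoint compartment.
COMPARTMENT_PNEC_UNITS = {
    "water": "mg/L",
    "microorganism": "mg/L",
    "soil": "mg/kg",
    "sediment": "mg/kg",
}


class NoEndpointError(LookupError):
    """No experimental endpoint available for a requested compartment."""


@dataclass(frozen=True)
class EcotoxEndpoint:
    """A single experimental toxicity endpoint with its assessment factor."""

    compartment: str  # water | microorganism | soil | sediment
    organism: str
    endpoint_type: str  # NOEC | EC50 | LC50
    value: float  # mg/L (water, microorganism) or mg/kg (soil, sediment)
    assessment_factor_AF: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENT_PNEC_UNITS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.endpoint_type not in ENDPOINT_TYPES:
            raise ValueError(f"unknown endpoint type {self.endpoint_type!r}")
        if self.value <= 0:
            raise ValueError("endpoint value must be strictly positive")
        if self.assessment_factor_AF is not None and self.assessment_factor_AF < 1:
            raise ValueError("assessment factor must be >= 1")

    @property
    def af(self) -> int:
        """Explicit AF, or the documented default for the endpoint type."""
        if self.assessment_factor_AF is not None:
            return self.assessment_factor_AF
        return DEFAULT_ASSESSMENT_FACTORS[self.endpoint_type]


@dataclass(frozen=True)
class PnecResult:
    compartment: str
    af_value: float | None
    ep_value: float | None
    selected: float
    method_used: str  # "AF" | "EP" | "min(AF,EP)"
    unit: str = ""


def pnec_af(endpoints: list[EcotoxEndpoint], compartment: str) -> float:
    """Assessment-factor PNEC: min over the compartment's endpoints of value/AF."""
    candidates = [e for e in endpoints if e.compartment == compartment]
    if not candidates:
        raise NoEndpointError(
            f"no AF-based PNEC: no experimental endpoint for compartment {compartment!r}"
        )
    return min(e.value / e.af for e in candidates)


def pnec_ep_soil(substance: SubstanceProperties, pnec_water: float) -> float:
    """Equilibrium-partitioning soil PNEC (mg/kg) from the water PNEC."""
    if pnec_water <= 0:
        raise ValueError("pnec_water must be strictly positive")
    return partition_factor(substance) * pnec_water


def pnec_ep_sediment(substance: SubstanceProperties, pnec_water: float) -> float:
    """Equilibrium-partitioning sediment PNEC (mg/kg) from the water PNEC."""
    if pnec_water <= 0:
        raise ValueError("pnec_water must be strictly positive")
    return (_SED_WATER_INTERCEPT + _SED_WATER_SLOPE * substance.koc) * pnec_water


def select_pnec(
    af_value: float | None, ep_value: float | None, compartment: str
) -> PnecResult:
    """Select the PNEC used for risk: the minimum of available candidates.

    When only one route produced a value (e.g. a compartment with no
    experimental endpoint has only the EP extrapolation) that value is used
    and the method recorded accordingly.
    """
    if af_value is None and ep_value is None:
        raise NoEndpointError(f"no PNEC candidate for compartment {compartment!r}")
    unit = COMPARTMENT_PNEC_UNITS[compartment]
    if af_value is None:
        return PnecResult(compartment, None, ep_value, ep_value, "EP", unit)
    if ep_value is None:
        return PnecResult(compartment, af_value, None, af_value, "AF", unit)
    return PnecResult(
        compartment, af_value, ep_value, min(af_value, ep_value), "min(AF,EP)", unit
    )


def derive_pnecs(
    endpoints: list[EcotoxEndpoint],
    substance: SubstanceProperties,
    sediment_af_from_water: bool = False,
) -> dict[str, PnecResult]:
    """Derive the PNEC per risk compartment (water, soil, sediment).

    The water PNEC pools the water and microorganism endpoints.  Soil takes
    min(AF, EP).  Sediment normally has no experimental endpoint and uses
    EP alone; set ``sediment_af_from_water`` to additionally admit the water
    AF value restated as a sediment candidate (a more conservative reading
    of sparse datasets; the min rule then applies across both).
    """
    water_eps = [e for e in endpoints if e.compartment in ("water", "microorganism")]
    if not water_eps:
        raise NoEndpointError(
            "no PNEC derivable: no endpoint for compartment 'water' "
            "(needed directly and for EP extrapolation)"
        )
    pnec_water = min(e.value / e.af for e in water_eps)

    results: dict[str, PnecResult] = {
        "water": select_pnec(pnec_water, None, "water")
    }

    soil_af = None
    try:
        soil_af = pnec_af(endpoints, "soil")
    except NoEndpointError:
        pass
    results["soil"] = select_pnec(soil_af, pnec_ep_soil(substance, pnec_water), "soil")

    sed_af = None
    try:
        sed_af = pnec_af(endpoints, "sediment")
    except NoEndpointError:
        if sediment_af_from_water:
            sed_af = pnec_water
    results["sediment"] = select_pnec(
        sed_af, pnec_ep_sediment(substance, pnec_water), "sediment"
    )
    return results
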