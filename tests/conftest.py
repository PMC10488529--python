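import pytest

from vet_era import (
    EcotoxEndpoint,
    ProductScenario,
    Regimen,
    SoilScenario,
    SubstanceProperties,
)
from vet_era.io_cli import generate_fixtures


@pytest.fixture
def soil():
    return SoilScenario()


@pytest.fixture
def scenario():
    """The worked-example product: 250 mg/g benzylpenicillin, three species."""
    return ProductScenario(
        name="benzylpenicillin potassium powder 250 mg/g",
        ai_content=250.0,
        regimens=(
            Regimen("piglet", 25.0, 4),
            Regimen("chicken", 10.0, 4),
            Regimen("turkey", 10.0, 4),
        ),
    )


@pytest.fixture
def substance():
    """Substance with everything derived from Koc (no overrides)."""
    return SubstanceProperties(
        name="penicillin G (benzylpenicillin)",
        molar_mass_MW=372.48,
        solubility_SOL=307.0,
        vapor_pressure_VP=2370.0,
        koc=421.0,
    )


@pytest.fixture
def substance_overridden(substance):
    """Substance carrying the documented worked-example overrides."""
    return SubstanceProperties(
        name=substance.name,
        molar_mass_MW=substance.molar_mass_MW,
        solubility_SOL=substance.solubility_SOL,
        vapor_pressure_VP=substance.vapor_pressure_VP,
        koc=substance.koc,
        partition_factor_override=7.69,
        sediment_pec_override=1721.0,
    )


@pytest.fixture
def endpoints():
    return [
        EcotoxEndpoint("water", "algae growth inhibition", "NOEC", 10.0, 10),
        EcotoxEndpoint(
            "microorganism", "activated sludge respiration inhibition", "EC50", 100.0, 100
        ),
        EcotoxEndpoint("soil", "earthworm", "NOEC", 2000.0, 100),
    ]


@pytest.fixture
def bundle(tmp_path):
    return generate_fixtures(tmp_path / "fixtures", seed=0)
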