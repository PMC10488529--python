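"""Fixed scenario constants and per-species husbandry defaults.

The Phase I soil exposure scenario assumes manure from intensively reared
animals is spread on arable land up to the EU nitrogen ceiling of
170 kg N/ha.  All animal-husbandry detail (body weight, production cycles
per year, nitrogen excreted per animal place and year) is collapsed into a
single composite factor H per species::

    H = BW * Ncycles / Ny        [kg bw * cycles / kg N]

so that the Phase I soil concentration needs only the dosing regimen and H.
The shipped H values are calibrated for the standard worst-case scenario;
assessments of other species or husbandry systems must supply their own H
(or the BW/Ncycles/Ny triple via :func:`composite_factor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path

import yaml


class UnknownSpeciesError(KeyError):
    """Raised when no husbandry defaults exist for a requested species."""


@dataclass(frozen=True)
class SoilScenario:
    """Constants of the manure-spreading soil scenario.

    Attributes
    ----------
    nitrogen_limit:
        Maximum areal nitrogen load applied with manure (kg N/ha).
    bulk_density:
        Dry soil bulk density (kg/m3).
    mixing_depth_phase1:
        Incorporation depth of the Phase I soil layer (m).
    mixing_depth_deep:
        Deeper mixing layer used for groundwater partitioning (m).
    hectare_area:
        Area of one hectare (m2).
    surface_water_dilution:
        Dimensionless dilution from pore water into surface water.
    """

    nitrogen_limit: float = 170.0
    bulk_density: float = 1500.0
    mixing_depth_phase1: float = 0.05
    mixing_depth_deep: float = 0.20
    hectare_area: float = 10_000.0
    surface_water_dilution: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "nitrogen_limit",
            "bulk_density",
            "mixing_depth_phase1",
            "mixing_depth_deep",
            "hectare_area",
            "surface_water_dilution",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"SoilScenario.{name} must be strictly positive")
        if self.mixing_depth_deep <= self.mixing_depth_phase1:
            raise ValueError(
                "mixing_depth_deep must exceed mixing_depth_phase1 "
                f"({self.mixing_depth_deep} <= {self.mixing_depth_phase1})"
            )


DEFAULT_SOIL = SoilScenario()


@dataclass(frozen=True)
class HusbandryDefaults:
    """Per-species husbandry parameters entering Phase I exposure."""

    species: str
    composite_factor_H: float
    fraction_treated_Fh: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.composite_factor_H <= 0:
            raise ValueError("composite_factor_H must be strictly positive")
        if not (0 < self.fraction_treated_Fh <= 1):
            raise ValueError("fraction_treated_Fh must lie in (0, 1]")


def composite_factor(
    body_weight_kg: float, cycles_per_year: float, n_excreted_kg_per_place_year: float
) -> float:
    """Combine the husbandry triple into the composite factor H."""
    if min(body_weight_kg, cycles_per_year, n_excreted_kg_per_place_year) <= 0:
        raise ValueError("husbandry parameters must be strictly positive")
    return body_weight_kg * cycles_per_year / n_excreted_kg_per_place_year


def _load_yaml_table(path: Path | None = None) -> dict:
    if path is None:
        text = (
            resources.files("vet_era").joinpath("data/husbandry.yaml").read_text()
        )
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "species" not in doc:
        raise ValueError("husbandry table must be a mapping with a 'species' key")
    return doc


def _registry_from_table(doc: dict) -> dict[str, HusbandryDefaults]:
    out: dict[str, HusbandryDefaults] = {}
    for species, row in doc["species"].items():
        out[species] = HusbandryDefaults(
            species=species,
            composite_factor_H=float(row["composite_factor_H"]),
            fraction_treated_Fh=float(row.get("fraction_treated_Fh", 1.0)),
            provenance=str(row.get("provenance", "")),
        )
    return out


@lru_cache(maxsize=1)
def _builtin_registry() -> dict[str, HusbandryDefaults]:
    return _registry_from_table(_load_yaml_table())


def load_registry(override_path: Path | str | None = None) -> dict[str, HusbandryDefaults]:
    """Packaged species table, optionally merged with a user override file.

    The override YAML uses the same schema; its species entries replace or
    extend the built-in ones by key.
    """
    registry = dict(_builtin_registry())
    if override_path is not None:
        registry.update(_registry_from_table(_load_yaml_table(Path(override_path))))
    return registry


def get_defaults(
    species: str, registry: dict[str, HusbandryDefaults] | None = None
) -> HusbandryDefaults:
    """Look up the husbandry defaults for ``species``.

    Raises
    ------
    UnknownSpeciesError
        If the species is not registered and no override supplies it.
        There is never a silent fallback.
    """
    reg = registry if registry is not None else _builtin_registry()
    try:
        return reg[species]
    except KeyError:
        known = ", ".join(sorted(reg)) or "<empty registry>"
        raise UnknownSpeciesError(
            f"no husbandry defaults for species {species!r}; known: {known}. "
            "Supply an override table or a composite factor H."
        ) from None
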