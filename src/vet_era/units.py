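"""Concentration units and conversions.

Two unit families are used throughout: mass-per-volume (waters, e.g. µg/L)
and mass-per-mass (soil and sediment dry weight, e.g. µg/kg).  Conversion
is only defined within a family; crossing families requires an explicit
model assumption and is rejected here.
"""

from __future__ import annotations

from dataclasses import dataclass


class UnitError(ValueError):
    """Unknown unit string or conversion across incompatible bases."""


# mass prefixes normalised to milligrams
_MASS_MG = {
    "ng": 1e-6,
    "ug": 1e-3,
    "µg": 1e-3,
    "mg": 1.0,
    "g": 1e3,
    "kg": 1e6,
}

_BASES = ("L", "kg")


def _parse(unit: str) -> tuple[float, str]:
    """Return (factor to mg per base, base) for a unit like 'µg/L'."""
    try:
        mass, base = unit.split("/")
    except ValueError:
        raise UnitError(f"malformed concentration unit {unit!r}") from None
    mass = mass.strip()
    base = base.strip()
    if mass not in _MASS_MG or base not in _BASES:
        raise UnitError(f"unknown concentration unit {unit!r}")
    return _MASS_MG[mass], base


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between concentration units of the same base.

    >>> convert(37.66, "µg/L", "mg/L")
    0.03766
    """
    f_from, b_from = _parse(from_unit)
    f_to, b_to = _parse(to_unit)
    if b_from != b_to:
        raise UnitError(
            f"cannot convert {from_unit!r} (per {b_from}) to {to_unit!r} (per {b_to})"
        )
    return value * f_from / f_to


@dataclass(frozen=True)
class Conc:
    """A concentration value tagged with its unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        _parse(self.unit)  # validate eagerly

    @property
    def base(self) -> str:
        """'L' for per-volume units, 'kg' for per-mass units."""
        return _parse(self.unit)[1]

    def to(self, unit: str) -> "Conc":
        return Conc(convert(self.value, self.unit, unit), unit)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.value:g} {self.unit}"
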