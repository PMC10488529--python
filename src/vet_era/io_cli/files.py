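"""Readers, writers and report rendering.

Hand-edited configuration is YAML, tabular data CSV, machine reports JSON.
Every schema carries a ``format_version`` field.  Readers validate strictly
and reject rather than coerce: unknown units, wrong unit bases and missing
columns raise :class:`SchemaError` with file and row context.

Human-readable rendering rounds concentrations to 2 decimals and risk
quotients to 3 decimals; stored values keep full precision.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from vet_era.effects import COMPARTMENT_PNEC_UNITS, EcotoxEndpoint
from vet_era.exposure import (
    PecMatrix,
    ProductScenario,
    Regimen,
    SubstanceProperties,
)
from vet_era.quant_calibration import CalibrationFit, CalibrationSeries
from vet_era.risk_engine import RiskMatrix
from vet_era.units import UnitError, convert

SUPPORTED_FORMAT_VERSION = 1


class SchemaError(ValueError):
    """An input file violates its documented schema."""


def _load_yaml(path: Path, kind: str) -> dict:
    try:
        doc = yaml.safe_load(Path(path).read_text())
    except OSError as exc:
        raise SchemaError(f"{path}: cannot read {kind} file: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: {kind} file must be a YAML mapping")
    version = doc.get("format_version")
    if version != SUPPORTED_FORMAT_VERSION:
        raise SchemaError(
            f"{path}: unsupported format_version {version!r} "
            f"(expected {SUPPORTED_FORMAT_VERSION})"
        )
    return doc


def _require(doc: dict, key: str, path: Path) -> object:
    if key not in doc:
        raise SchemaError(f"{path}: missing required key {key!r}")
    return doc[key]


def read_scenario(path: Path | str) -> ProductScenario:
    """Read a product scenario YAML file."""
    path = Path(path)
    doc = _load_yaml(path, "scenario")
    product = _require(doc, "product", path)
    rows = _require(doc, "regimens", path)
    if not isinstance(rows, list) or not rows:
        raise SchemaError(f"{path}: 'regimens' must be a non-empty list")
    regimens = []
    seen = set()
    for i, row in enumerate(rows, start=1):
        try:
            species = str(row["species"])
            regimen = Regimen(
                species=species,
                dose_D=float(row["dose_mg_per_kg_bw_day"]),
                duration_Ad=int(row["duration_days"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: regimen #{i}: {exc}") from exc
        if species in seen:
            raise SchemaError(f"{path}: regimen #{i}: duplicate species {species!r}")
        seen.add(species)
        regimens.append(regimen)
    try:
        return ProductScenario(
            name=str(_require(product, "name", path)),
            ai_content=float(_require(product, "ai_content_mg_per_g", path)),
            regimens=tuple(regimens),
            route=str(product.get("route", "oral, drinking water")),
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_substance(path: Path | str, use_overrides: bool = False) -> SubstanceProperties:
    """Read a substance properties YAML file.

    ``use_overrides`` applies the optional ``overrides`` block (verbatim
    partition factor, stored sediment PEC); by default the block is ignored
    and everything is computed from Koc.
    """
    path = Path(path)
    doc = _load_yaml(path, "substance")
    sub = _require(doc, "substance", path)
    overrides = doc.get("overrides") or {}
    try:
        return SubstanceProperties(
            name=str(_require(sub, "name", path)),
            molar_mass_MW=float(_require(sub, "molar_mass", path)),
            solubility_SOL=float(_require(sub, "water_solubility_mg_per_L", path)),
            vapor_pressure_VP=float(_require(sub, "vapor_pressure", path)),
            koc=float(_require(sub, "koc_L_per_kg", path)),
            partition_factor_override=(
                float(overrides["partition_factor_L_per_kg"])
                if use_overrides and "partition_factor_L_per_kg" in overrides
                else None
            ),
            sediment_pec_override=(
                float(overrides["sediment_pec_ug_per_kg"])
                if use_overrides and "sediment_pec_ug_per_kg" in overrides
                else None
            ),
        )
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: {exc}") from exc


_ENDPOINT_COLUMNS = [
    "compartment",
    "organism",
    "endpoint_type",
    "value",
    "unit",
    "assessment_factor",
]


def read_endpoints(path: Path | str) -> list[EcotoxEndpoint]:
    """Read an ecotoxicity endpoint CSV.

    Columns: compartment, organism, endpoint_type, value, unit,
    assessment_factor (empty -> documented default AF ladder).  Values are
    normalized to mg/L (water, microorganism) or mg/kg (soil, sediment);
    a unit of the wrong base for the compartment is a schema error.
    """
    path = Path(path)
    endpoints: list[EcotoxEndpoint] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c for c in _ENDPOINT_COLUMNS if c not in reader.fieldnames]:
            raise SchemaError(
                f"{path}: endpoint CSV must have columns {', '.join(_ENDPOINT_COLUMNS)}"
            )
        for line_no, row in enumerate(reader, start=2):
            compartment = row["compartment"].strip()
            if compartment not in COMPARTMENT_PNEC_UNITS:
                raise SchemaError(
                    f"{path}:{line_no}: unknown compartment {compartment!r}"
                )
            target_unit = COMPARTMENT_PNEC_UNITS[compartment]
            try:
                value = convert(float(row["value"]), row["unit"].strip(), target_unit)
            except UnitError as exc:
                raise SchemaError(
                    f"{path}:{line_no}: unit {row['unit']!r} invalid for "
                    f"compartment {compartment!r}: {exc}"
                ) from exc
            except ValueError as exc:
                raise SchemaError(f"{path}:{line_no}: bad value: {exc}") from exc
            af_raw = (row.get("assessment_factor") or "").strip()
            try:
                endpoints.append(
                    EcotoxEndpoint(
                        compartment=compartment,
                        organism=row["organism"].strip(),
                        endpoint_type=row["endpoint_type"].strip(),
                        value=value,
                        assessment_factor_AF=int(af_raw) if af_raw else None,
                    )
                )
            except ValueError as exc:
                raise SchemaError(f"{path}:{line_no}: {exc}") from exc
    if not endpoints:
        raise SchemaError(f"{path}: endpoint CSV contains no rows")
    return endpoints


def read_calibration(path: Path | str) -> CalibrationSeries:
    """Read a calibration CSV with columns concentration_ng_per_L, replicate, area."""
    path = Path(path)
    by_level: dict[float, list[float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"concentration_ng_per_L", "replicate", "area"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path}: calibration CSV must have columns {', '.join(sorted(required))}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                conc = float(row["concentration_ng_per_L"])
                area = float(row["area"])
            except ValueError as exc:
                raise SchemaError(f"{path}:{line_no}: bad number: {exc}") from exc
            by_level.setdefault(conc, []).append(area)
    try:
        return CalibrationSeries(
            levels=tuple((c, tuple(areas)) for c, areas in sorted(by_level.items()))
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_samples(path: Path | str) -> list[dict]:
    """Read a sample CSV (sample_id, analyte, area, retention_time_min)."""
    path = Path(path)
    samples = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "analyte", "area"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise SchemaError(
                f"{path}: sample CSV must have columns {', '.join(sorted(required))}"
            )
        for line_no, row in enumerate(reader, start=2):
            try:
                samples.append(
                    {
                        "sample_id": row["sample_id"].strip(),
                        "analyte": row["analyte"].strip(),
                        "area": float(row["area"]),
                        "retention_time": (
                            float(row["retention_time_min"])
                            if (row.get("retention_time_min") or "").strip()
                            else None
                        ),
                    }
                )
            except ValueError as exc:
                raise SchemaError(f"{path}:{line_no}: bad number: {exc}") from exc
    if not samples:
        raise SchemaError(f"{path}: sample CSV contains no rows")
    return samples


# --- report rendering -------------------------------------------------------

_CONC_DECIMALS = 2
_RISK_DECIMALS = 3


def build_report(
    scenario: ProductScenario,
    substance: SubstanceProperties,
    result: RiskMatrix,
) -> dict:
    """Assemble the machine-readable assessment report."""
    pec: PecMatrix = result.pec
    report: dict = {
        "format_version": SUPPORTED_FORMAT_VERSION,
        "product": {
            "name": scenario.name,
            "ai_content_mg_per_g": scenario.ai_content,
            "route": scenario.route,
        },
        "substance": {
            "name": substance.name,
            "molar_mass": substance.molar_mass_MW,
            "water_solubility_mg_per_L": substance.solubility_SOL,
            "vapor_pressure": substance.vapor_pressure_VP,
            "koc_L_per_kg": substance.koc,
            "partition_factor_override": substance.partition_factor_override,
            "sediment_pec_override_ug_per_kg": substance.sediment_pec_override,
        },
        "phase1": {
            sp: {
                "pec_soil_ug_per_kg": pec.value(sp, "soil").value if pec else None,
                "triggered": flag,
            }
            for sp, flag in result.phase1_triggered.items()
        },
        "worst_case_species": result.worst_case_species,
        "conclusion": result.conclusion,
    }
    if pec is not None:
        report["pec_matrix"] = [
            {
                "species": sp,
                "compartment": comp,
                "value": conc.value,
                "display": round(conc.value, _CONC_DECIMALS),
                "unit": conc.unit,
            }
            for (sp, comp), conc in pec.entries.items()
        ]
        report["pec_headline"] = {
            comp: {"value": c.value, "display": round(c.value, _CONC_DECIMALS), "unit": c.unit}
            for comp, c in pec.headline.items()
        }
    if result.pnec:
        report["pnec"] = {
            comp: {
                "af_value": res.af_value,
                "ep_value": res.ep_value,
                "selected": res.selected,
                "display": round(res.selected, _CONC_DECIMALS),
                "method_used": res.method_used,
                "unit": res.unit,
            }
            for comp, res in result.pnec.items()
        }
    if result.headline:
        report["risk"] = {
            comp: {
                "pec": pair[0].value,
                "pec_unit": pair[0].unit,
                "pnec": pair[1].value,
                "pnec_unit": pair[1].unit,
                "R": result.headline[comp],
                "display": round(result.headline[comp], _RISK_DECIMALS),
            }
            for comp, pair in result.headline_pairs.items()
        }
        report["risk_matrix"] = [
            {"species": sp, "compartment": comp, "R": r,
             "display": round(r, _RISK_DECIMALS)}
            for (sp, comp), r in result.entries.items()
        ]
    if result.refined_headline:
        report["risk_refined"] = {
            comp: {"R": r, "display": round(r, _RISK_DECIMALS)}
            for comp, r in result.refined_headline.items()
        }
    report["trace"] = [asdict(rec) for rec in result.trace]
    return report


def write_report(report: dict, path: Path | str) -> None:
    Path(path).write_text(json.dumps(report, indent=2, ensure_ascii=False) + "\n")


def write_fit(fit: CalibrationFit, path: Path | str) -> None:
    Path(path).write_text(json.dumps(asdict(fit), indent=2) + "\n")


def write_pec_csv(pec: PecMatrix, path: Path | str) -> None:
    """Serialize a PEC matrix in long format (species, compartment, value, unit)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "compartment", "value", "unit"])
        for (sp, comp), conc in pec.entries.items():
            writer.writerow([sp, comp, repr(conc.value), conc.unit])


def render_markdown(report: dict) -> str:
    """Human-readable report: PEC, PNEC and risk tables plus the conclusion."""
    lines = [
        f"# Environmental risk assessment: {report['product']['name']}",
        "",
        f"Active ingredient: {report['substance']['name']} "
        f"({report['product']['ai_content_mg_per_g']} mg/g)",
        "",
        "## Phase I soil concentrations",
        "",
        "| species | PECsoil (µg/kg) | > 100 µg/kg trigger |",
        "|---|---|---|",
    ]
    for sp, row in report["phase1"].items():
        lines.append(
            f"| {sp} | {row['pec_soil_ug_per_kg']:.2f} | "
            f"{'yes' if row['triggered'] else 'no'} |"
        )
    lines.append("")
    if "pec_headline" in report:
        lines += [
            f"Worst case species: **{report['worst_case_species']}**",
            "",
            "## Predicted environmental concentrations (worst case)",
            "",
            "| compartment | PEC | unit |",
            "|---|---|---|",
        ]
        for comp, row in report["pec_headline"].items():
            lines.append(f"| {comp} | {row['display']:.2f} | {row['unit']} |")
        lines.append("")
    if "pnec" in report:
        lines += [
            "## Predicted no-effect concentrations",
            "",
            "| compartment | AF value | EP value | selected | method | unit |",
            "|---|---|---|---|---|---|",
        ]
        for comp, row in report["pnec"].items():
            af = "-" if row["af_value"] is None else f"{row['af_value']:.2f}"
            ep = "-" if row["ep_value"] is None else f"{row['ep_value']:.2f}"
            lines.append(
                f"| {comp} | {af} | {ep} | {row['display']:.2f} | "
                f"{row['method_used']} | {row['unit']} |"
            )
        lines.append("")
    if "risk" in report:
        lines += [
            "## Risk quotients (worst case)",
            "",
            "| compartment | PEC | PNEC | R (PEC/PNEC) |",
            "|---|---|---|---|",
        ]
        for comp, row in report["risk"].items():
            lines.append(
                f"| {comp} | {round(row['pec'], _CONC_DECIMALS)} {row['pec_unit']} | "
                f"{round(row['pnec'], _CONC_DECIMALS)} {row['pnec_unit']} | "
                f"{row['display']:.3f} |"
            )
        lines.append("")
    lines += [f"**Conclusion:** `{report['conclusion']}`", ""]
    return "\n".join(lines)
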