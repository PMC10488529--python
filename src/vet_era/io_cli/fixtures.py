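"""Worked-example fixture bundle.

Packages the benzylpenicillin product scenario as ready-to-run input
files: scenario and substance YAML, ecotoxicity endpoint CSV, a synthetic
calibration series (areas from the validated line plus seeded Gaussian
noise) and a surface-water sample CSV.  Generation is deterministic for a
fixed seed, down to the byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Calibration line of the validated analytical method (area units).
CAL_SLOPE = 46.5  # area per ng/L
CAL_INTERCEPT = 238.982  # area; back-solved so area 1748 -> 32.452 ng/L
CAL_LEVELS_NG_PER_L = (4.0, 20.0, 100.0, 500.0, 5000.0)
CAL_REPLICATES = 3
CAL_NOISE_SD = 0.5  # area units

_SCENARIO_YAML = """\
format_version: 1
product:
  name: benzylpenicillin potassium powder 250 mg/g
  ai_content_mg_per_g: 250
  route: oral, drinking water
regimens:
  - species: piglet
    dose_mg_per_kg_bw_day: 25
    duration_days: 4
  - species: chicken
    dose_mg_per_kg_bw_day: 10
    duration_days: 4
  - species: turkey
    dose_mg_per_kg_bw_day: 10
    duration_days: 4
"""

_SUBSTANCE_YAML = """\
format_version: 1
substance:
  name: penicillin G (benzylpenicillin)
  molar_mass: 372.48
  water_solubility_mg_per_L: 307
  vapor_pressure: 2370
  koc_L_per_kg: 421
# Documented worked-example overrides; applied only with use_overrides /
# --use-overrides.  The stored partition factor differs slightly from the
# Koc-derived one (7.544) and the stored sediment PEC from the
# suspended-matter estimate; both reproduce the published assessment.
overrides:
  partition_factor_L_per_kg: 7.69
  sediment_pec_ug_per_kg: 1721
"""

_ENDPOINTS_CSV = """\
compartment,organism,endpoint_type,value,unit,assessment_factor
water,algae growth inhibition,NOEC,10,mg/L,10
microorganism,activated sludge respiration inhibition,EC50,100,mg/L,100
soil,earthworm,NOEC,2000,mg/kg,100
"""

# sample 3 carries the quantifiable residue; the rest sit at baseline
_SAMPLES = (
    ("river-1", "penicillin G", 239.2, 5.93),
    ("river-2", "penicillin G", 238.6, 5.91),
    ("river-3", "penicillin G", 1748.0, 5.92),
    ("river-4", "penicillin G", 239.4, 5.94),
)


@dataclass(frozen=True)
class FixtureBundle:
    """Paths of a generated worked-example bundle."""

    scenario: Path
    substance: Path
    endpoints: Path
    calibration: Path
    samples: Path


def generate_fixtures(outdir: Path | str, seed: int = 0) -> FixtureBundle:
    """Write the complete fixture bundle into ``outdir``.

    Calibration peak areas are simulated from the validated line with
    Gaussian noise (sd ``CAL_NOISE_SD``); the generator is seeded, so two
    runs with the same seed produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = FixtureBundle(
        scenario=outdir / "scenario.yaml",
        substance=outdir / "substance.yaml",
        endpoints=outdir / "endpoints.csv",
        calibration=outdir / "calibration.csv",
        samples=outdir / "samples.csv",
    )
    bundle.scenario.write_text(_SCENARIO_YAML)
    bundle.substance.write_text(_SUBSTANCE_YAML)
    bundle.endpoints.write_text(_ENDPOINTS_CSV)

    rng = np.random.default_rng(seed)
    rows = ["concentration_ng_per_L,replicate,area"]
    for conc in CAL_LEVELS_NG_PER_L:
        for rep in range(1, CAL_REPLICATES + 1):
            area = CAL_SLOPE * conc + CAL_INTERCEPT + rng.normal(0.0, CAL_NOISE_SD)
            rows.append(f"{conc:g},{rep},{area:.3f}")
    bundle.calibration.write_text("\n".join(rows) + "\n")

    rows = ["sample_id,analyte,area,retention_time_min"]
    for sample_id, analyte, area, rt in _SAMPLES:
        rows.append(f"{sample_id},{analyte},{area:.1f},{rt:.2f}")
    bundle.samples.write_text("\n".join(rows) + "\n")
    return bundle
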