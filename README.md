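# vet-era

Tiered environmental risk assessment (ERA) of veterinary medicinal products,
plus the linear-calibration arithmetic (LOD/LOQ/RSD, sample quantification)
used to compare predicted with measured surface-water concentrations.

The package walks the standard two-phase decision tree for manure-spread
residues of a veterinary active ingredient:

1. **Phase I** — total-residue soil concentration (PECsoil) per treated
   species under the 170 kg N/ha manure-spreading scenario; assessment
   stops if no species exceeds the 100 µg/kg trigger.
2. **Phase II, Tier A** — groundwater, surface-water and sediment PECs from
   the worst-case soil PEC via Koc equilibrium partitioning; PNECs per
   compartment by the assessment-factor and equilibrium-partitioning
   methods; risk quotients R = PEC/PNEC with stop/refine logic and a full
   decision trace.

Modules: `guideline_data` (scenario constants, per-species composite
husbandry factors), `exposure` (PECs), `effects` (PNECs), `risk_engine`
(decision tree), `quant_calibration` (calibration, LOD/LOQ, RSD,
quantification, measured-vs-predicted ratios), `io_cli` (YAML/CSV/JSON
formats, worked-example fixture bundle, CLI).

## CLI

Generate the complete worked-example input bundle (a 250 mg/g
benzylpenicillin product for piglets, chickens and turkeys), then run the
assessment:

```sh
vet-era fixtures --out example --seed 0
vet-era assess --scenario example/scenario.yaml \
               --substance example/substance.yaml \
               --endpoints example/endpoints.csv \
               --use-overrides --out report.json --markdown report.md
```

`--use-overrides` applies the override block stored in the substance file
(a verbatim soil–water partition factor and a stored sediment PEC) instead
of deriving everything from Koc; the worked example ships with both.

Other subcommands:

```sh
vet-era pec --scenario example/scenario.yaml --substance example/substance.yaml
vet-era pnec --substance example/substance.yaml --endpoints example/endpoints.csv
vet-era calibrate --series example/calibration.csv
vet-era quantify --series example/calibration.csv --samples example/samples.csv \
                 --pec-sw 37.66 --pnec-water 1.0
```

`vet-era -v …` logs every formula evaluation (the decision trace) to stderr.

User husbandry tables (`--husbandry table.yaml`) merge with the built-in
species registry by key; unknown species without an override are a hard
error, never a silent fallback.

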