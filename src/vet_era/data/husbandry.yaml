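format_version: 1
# Composite husbandry factors H = BW * Ncycles / Ny (kg bw * cycles / kg N
# excreted per place-year) for the worst-case intensive-rearing scenario.
# Calibrated so the Phase I formula with Ad = 4 d and Fh = 1 reproduces the
# standard scenario soil loads for these species to 4 significant figures.
species:
  piglet:
    composite_factor_H: 38.3329
    fraction_treated_Fh: 1.0
    provenance: calibrated worst-case intensive rearing, 4-day treatment
  chicken:
    composite_factor_H: 39.1301
    fraction_treated_Fh: 1.0
    provenance: calibrated worst-case intensive rearing (broiler), 4-day treatment
  turkey:
    composite_factor_H: 19.5
    fraction_treated_Fh: 1.0
    provenance: calibrated worst-case intensive rearing, 4-day treatment
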