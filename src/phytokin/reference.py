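"""Published reference values for red onion (*Allium cepa* L.) skin extract.

Thermal degradation of the extract's total anthocyanins content (TAC) and
DPPH antioxidant activity was characterized at five temperatures between 75
and 155 °C; enzyme inhibition (IC50) was measured against four enzymes linked
to metabolic syndrome. The printed summary statistics below serve as inputs
for desk-scale recomputation: rate constants feed the Arrhenius regression,
decimal reduction times feed the z-value regression, and IC50 mean ± SD
summaries feed the Tukey letter comparison.

All rate constants are in min^-1 (the tables print k x 10^-2), times in min,
temperatures in °C, energies in kJ/mol and IC50s in ug/mL.
"""

from __future__ import annotations

#: First-order degradation rate constants k (min^-1) by temperature (°C).
TAC_RATE_CONSTANTS: dict[float, float] = {
    75.0: 0.0069,
    95.0: 0.0138,
    115.0: 0.0253,
    135.0: 0.0737,
    155.0: 0.1865,
}

ANTIOXIDANT_RATE_CONSTANTS: dict[float, float] = {
    75.0: 0.0048,
    95.0: 0.0069,
    115.0: 0.0085,
    135.0: 0.0104,
    155.0: 0.0133,
}

#: Printed half-life values t1/2 (min) by temperature (°C).
TAC_HALF_LIVES: dict[float, float] = {
    75.0: 100.32,
    95.0: 50.16,
    115.0: 27.36,
    135.0: 9.41,
    155.0: 3.72,
}

ANTIOXIDANT_HALF_LIVES: dict[float, float] = {
    75.0: 143.32,
    95.0: 100.33,
    115.0: 81.34,
    135.0: 66.88,
    155.0: 51.89,
}

#: Printed decimal reduction times D (min) by temperature (°C).
TAC_D_VALUES: dict[float, float] = {
    75.0: 333.33,
    95.0: 166.67,
    115.0: 90.91,
    135.0: 31.25,
    155.0: 12.35,
}

ANTIOXIDANT_D_VALUES: dict[float, float] = {
    75.0: 476.19,
    95.0: 333.33,
    115.0: 270.27,
    135.0: 222.22,
    155.0: 172.41,
}

#: Printed cross-temperature parameters: activation energy (kJ/mol), z (°C).
TAC_ACTIVATION_ENERGY = 50.77
ANTIOXIDANT_ACTIVATION_ENERGY = 15.13
TAC_Z_VALUE = 55.56
ANTIOXIDANT_Z_VALUE = 188.68

#: Printed activation thermodynamics by absolute temperature (K, printed as
#: °C + 273): (dH kJ/mol, dG kJ/mol, dS J/(mol*K)).
TAC_THERMODYNAMICS: dict[float, tuple[float, float, float]] = {
    348.0: (47.88, 111.91, -184.02),
    368.0: (47.71, 116.40, -186.65),
    388.0: (47.54, 120.94, -189.16),
    408.0: (47.38, 123.72, -187.12),
    428.0: (47.21, 126.65, -185.61),
}

ANTIOXIDANT_THERMODYNAMICS: dict[float, tuple[float, float, float]] = {
    348.0: (12.24, 112.95, -289.39),
    368.0: (12.07, 118.52, -289.25),
    388.0: (11.91, 124.45, -290.07),
    408.0: (11.74, 130.37, -290.77),
    428.0: (11.57, 136.03, -290.79),
}

#: Enzyme-inhibition IC50 summaries (mean ug/mL, SD, n) with the published
#: compact letters, per enzyme column: (sample, mean, sd, n, letter).
IC50_SUMMARIES: dict[str, list[tuple[str, float, float, int, str]]] = {
    "alpha_amylase": [
        ("extract", 1.02, 0.30, 3, "a"),
        ("acarbose", 4.49, 0.44, 3, "b"),
    ],
    "alpha_glucosidase": [
        ("extract", 0.57, 0.16, 3, "a"),
        ("acarbose", 2.09, 0.14, 3, "b"),
    ],
    "lipase": [
        ("extract", 4.57, 0.86, 3, "a"),
        ("orlistat", 3.18, 0.33, 3, "a"),
    ],
    "lox": [
        ("extract", 2.40, 0.71, 3, "a"),
        ("quercetin", 1.95, 0.20, 3, "a"),
    ],
}

#: Extract IC50 point estimates (ug/mL) used as generator truth scales.
EXTRACT_IC50: dict[str, float] = {
    "alpha_amylase": 1.02,
    "alpha_glucosidase": 0.57,
    "lipase": 4.57,
    "lox": 2.40,
}

#: Assay concentrations tested (ug/mL extract).
ASSAY_CONCENTRATIONS: tuple[float, float, float] = (0.5, 1.0, 5.0)

#: Heat-treatment design: temperatures (°C) and sampling times (min).
STUDY_TEMPERATURES: tuple[float, ...] = (75.0, 95.0, 115.0, 135.0, 155.0)
STUDY_TIMES: tuple[float, ...] = (0.0, 15.0, 30.0, 45.0, 60.0)
STUDY_REPLICATES = 3
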