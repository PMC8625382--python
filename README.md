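# phytokin

Thermal degradation kinetics, activation thermodynamics and enzyme-inhibition
inference for phytochemical extracts — built around the red onion (*Allium
cepa* L.) skin extract, whose anthocyanins and antioxidant activity degrade
measurably during pasteurization/sterilization-range heating (75–155 °C), and
whose extracts inhibit enzymes linked to metabolic syndrome (α-amylase,
α-glucosidase, pancreatic lipase, lipoxygenase).

The package is for food scientists and phytochemists who have (or simulate)
time–temperature degradation series and dose–response inhibition tables and
want the standard derived parameters with uncertainties, in reproducible,
tested code.

## The models

**Primary kinetics.** Each response C (total anthocyanins content TAC, or
DPPH antioxidant activity) decays first-order at temperature T:

    C/C0 = exp(-k t),      t1/2 = ln 2 / k,      D = ln 10 / k

k is fitted by OLS on ln(C/C0) vs t, per replicate, reported mean ± SD.

**Secondary models.** Across temperatures,

    Arrhenius:  ln k = ln A − Ea / (R T_K)        → activation energy Ea
    TDT model:  log10 D linear in T (°C), z = −1/slope

**Activation thermodynamics (Eyring).** With k in s⁻¹,

    ΔH = Ea − R T,   ΔG = R T ln(k_B T / (h k_s)),   ΔS = (ΔH − ΔG)/T

**Bioassay.** IC50 from the linear-in-log dose–response,
inhibition% = b0 + b1·log10(c), IC50 = 10^((50−b0)/b1), with delta-method SE;
group comparison by one-way ANOVA + Tukey HSD reconstructed from
(mean, SD, n) summaries, results as compact letters.

**Spectro assays.** pH-differential total anthocyanins (mg C3G/g DW),
standard-curve quantification for total phenolics (GAE) and DPPH (TE).

A synthetic-data module generates all of these measurement types by inverting
the respective models, so the whole pipeline is testable end to end without
any download.

## Worked example

```sh
python examples/degradation_kinetics.py
```

```
T (°C)   k x100 (1/min)   t1/2 (min)   D (min)    R^2
    75       0.71 ± 0.03      98.32     326.60   0.981
    95       1.36 ± 0.02      51.12     169.82   0.997
   115       2.57 ± 0.02      26.92      89.43   0.998
   135       7.37 ± 0.05       9.40      31.23   1.000
   155      18.59 ± 0.07       3.73      12.39   1.000

Ea = 50.63 ± 4.87 kJ/mol (R^2 = 0.97)
z  = 55.91 ± 3.49 °C     (R^2 = 0.99)
```

Each row is one temperature's first-order fit to simulated triplicate decay
curves (3% multiplicative noise): the rate constant k rises ~27-fold from 75
to 155 °C while the half-life t1/2 falls from ~98 to ~3.7 min — anthocyanins
are far more heat-labile at sterilization temperatures. Ea ≈ 51 kJ/mol
quantifies that temperature sensitivity; z ≈ 56 °C says a 56 °C rise divides
the decimal reduction time by ten. The other examples cover the
thermodynamic table (`examples/thermodynamics.py`), IC50 inference and Tukey
letters (`examples/ic50_inference.py`) and the spectrophotometric formulas
(`examples/spectro_quantification.py`).

A thin CLI wraps the same functions:

```sh
phytokin simulate --noise-cv 0.03 --seed 1 --out run.csv
phytokin report --input run.csv --outdir report/
phytokin reproduce --outdir reference_report/
```

## Layout

- `src/phytokin/` — library: `kinetics`, `secondary`, `thermo`, `bioassay`,
  `spectro`, `simulate`, `io`, `pipeline`, `reference` (published summary
  inputs), `cli`
- `examples/` — narrative scripts, one per capability
- `tests/` — pytest suite (unit, property and acceptance tests)
- `docs/methods.md` — models, assumptions, defaults and limitations
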