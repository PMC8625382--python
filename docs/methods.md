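# Methods

## Scope and data model

The package analyses two measurement families from heat-treatment studies of
phytochemical extracts:

1. **Degradation series** — a response (total anthocyanins content, TAC, in
   mg cyanidin-3-O-glucoside equivalents/g DW; or DPPH antioxidant activity,
   mM Trolox equivalents/g DW) measured over heating time at several fixed
   temperatures, in replicate tubes. The reference design is 75, 95, 115,
   135, 155 °C × 0, 15, 30, 45, 60 min × 3 replicates.
2. **Dose–response tables** — % enzyme inhibition at a few extract
   concentrations (reference: 0.5, 1, 5 µg/mL, triplicate) for α-amylase,
   α-glucosidase, pancreatic lipase and lipoxygenase.

## Kinetic model and estimation

First-order decay, C(t) = C0·exp(−k t). Estimation is OLS on the linearized
form ln(C/C0) vs t with a **free intercept** (default): the intercept absorbs
measurement error in the t = 0 reference, so the slope is not leveraged by a
single noisy point. Alternatives `through_origin` and `nonlinear`
(exponential least squares) are provided as config switches; all three agree
exactly on noiseless data.

- **C0 policy**: each replicate's own t = 0 reading (default), or the mean
  t = 0 across replicates.
- **Replicates**: fitted separately; k is reported as mean ± SD across
  replicate fits, matching how triplicate designs are summarized. A pooled
  single regression is available (`pooled=True`).
- **Non-positive responses** (possible under heavy degradation plus noise)
  are excluded with a warning, not floored — flooring at a small constant
  would bias the slope. A replicate needs ≥ 3 usable time points.
- Derived: t1/2 = ln2/k, D = ln10/k (both min); undefined (NaN in tables,
  explicit error from the scalar functions) when k ≤ 0. The identity
  t1/2·ln10 = D·ln2 is asserted on every fit object.

## Secondary models

- **Arrhenius**: unweighted OLS of ln k on 1/T_K, T_K = T°C + 273.15;
  Ea = −slope·R/1000 (kJ/mol) with R = 8.314 J/(mol·K); the reported Ea SE is
  the regression slope SE. Unweighted because per-k uncertainties enter only
  as replicate SDs, and the published cross-temperature parameters are
  reproduced by the unweighted fit.
- **z-value**: OLS of log10 D on temperature in °C (the slope is
  offset-invariant, so Kelvin gives the identical z); z = −1/slope, SE by the
  delta method (se(z) = se(slope)/slope²). z is the temperature rise that
  divides D by ten.
- Consistency: for exactly-Arrhenius rates, z ≈ ln10·R·T_K²/Ea around the
  design's mean absolute temperature; over the 80 °C span of the reference
  design the fitted z agrees with this closed form within 3%
  (`z_from_arrhenius`).

## Activation thermodynamics

Per temperature, with the cross-temperature Ea and that temperature's k:
ΔH = Ea − R·T/1000 (kJ/mol); ΔG = R·T·ln(k_B·T/(h·k_s))/1000 with k
converted min⁻¹ → s⁻¹ (the ÷60 is fixed: only s⁻¹ rates reproduce published
ΔG tables from published per-minute rate constants); ΔS = (ΔH − ΔG)·1000/T
(J/(mol·K)). The transmission coefficient is 1. ΔH uses the single global Ea
(not temperature-windowed estimates). Uncertainties are first-order
delta-method SEs: ΔH inherits the Ea regression SE, ΔG propagates the
replicate SD of k via R·T·(sd_k/k)/1000, ΔS combines the two in quadrature;
they are labelled delta-method SEs and are not claimed to reproduce any
published ± values, whose provenance is unstated. The identity
ΔS·T/1000 = ΔH − ΔG is asserted per row, and every row satisfies the Eyring
round trip k → (ΔH, ΔS) → k to machine precision (`eyring_rate`).

## IC50 inference

With only three concentrations a four-parameter logistic is under-determined,
so the estimator is the field's linear-in-log read-off: OLS of inhibition %
on log10 concentration over all replicate points, IC50 = 10^((50−b0)/b1).
The SE comes from the delta method on the OLS parameter covariance. A
non-positive slope raises an explicit no-crossing error; an IC50 outside the
tested range is returned but flagged `extrapolated`.

**Tukey letters from summaries.** Published comparisons give only
mean ± SD, n per sample, so one-way ANOVA and Tukey HSD are reconstructed
from summary statistics: pooled within-group variance
MSW = Σ(nᵢ−1)sᵢ²/(N−g), pairwise q = |mᵢ−mⱼ|/√(MSW·(1/nᵢ+1/nⱼ)/2), p from
the studentized range with N−g df and g groups, α = 0.05. The compact letter
display uses the insert-and-absorb algorithm ordered from the smallest mean;
the summary route is cross-checked in the tests against raw-data Tukey HSD
(statsmodels) on samples constructed to have exactly the given mean and SD.
Groups with n < 2 are excluded with a warning.

## Spectrophotometric assays

pH-differential: A = (A520−A700)_pH1.0 − (A520−A700)_pH4.5;
TAC (mg/L) = A·MW·DF·1000/(ε·l) with the cyanidin-3-O-glucoside constants
MW = 449.2 g/mol, ε = 26 900 L/(mol·cm) (the standard constants of the
method), divided by the sample loading (g DW/L) for the per-gram basis.
Negative A reports 0 with a warning (no monomeric anthocyanin signal).
Total phenolics (gallic acid equivalents) and DPPH (Trolox equivalents) go
through OLS standard curves (≥ 3 points); quantification is linear in the
dilution factor and inverse-linear in sample loading, asserted by scaling
tests. Calibration ranges and replicate counts are user choices; the
defaults in the examples are documented, not inferred from any source.

## Synthetic-data generator

The generator inverts each model:

- **Degradation**: response = C0·exp(−k t)·ε with ε lognormal, median 1,
  CV = `noise_cv`, independent across tubes and time points (each tube is a
  separate sealed sample; no autocorrelation). Multiplicative noise because
  spectrophotometric error scales with signal. Default `noise_cv = 0.03`,
  consistent with the 3–12% relative SDs typical of fitted rate constants in
  such designs; the raw-absorbance noise magnitude is a calibration choice,
  not a published value.
- **Arrhenius sets**: exact k(T) = exp(lnA − Ea·1000/(R·T_K)) for recovery
  tests (`ln_a_for_k_at` anchors the line through a chosen (T, k)).
- **Dose–response**: inhibition = 50 + slope·(log10 c − log10 IC50) +
  N(0, `noise_sd`), clipped to [0, 100] (inhibition is bounded; noise is
  additive on the percentage scale). Default slope 25·ln10 ≈ 57.6 %/decade —
  the tangent slope of a unit-Hill-coefficient logistic at its midpoint, the
  canonical dose–response steepness. Default `noise_sd` in examples: 3
  percentage points.

What passing tests show — and don't. The generator reproduces the *assumed*
statistical structure (exact first-order decay, exact linear-in-log
response, independent noise). Real extracts can deviate: biphasic or
matrix-dependent kinetics, Hill coefficients ≠ 1, heteroscedastic or
correlated replicate error, pipetting drift. Recovery results here therefore
validate the estimators under the stated model, not the model itself.

## Numerical choices and problem sizes

- Fits use `scipy.stats.linregress` / `statsmodels.OLS`; no iterative
  optimization except the optional `nonlinear` kinetic fit (curve_fit).
- CSV interchange writes floats as shortest round-trip reprs and reads with
  round-trip parsing, so write→read is lossless; report tables are written
  at 10 significant digits. Pipelines are deterministic given config; all
  randomness flows through `numpy.random.default_rng(seed)`.
- Monte-Carlo sizes: 500 simulations for rate-constant and IC50 recovery
  checks, 200 for calibration-slope recovery, 200 replicates for the
  lognormal median check — sizes at which the sampling error of the checked
  statistic is comfortably below the asserted tolerance, while the whole
  suite stays fast.
- Kelvin conversion uses 273.15. Published thermodynamic tables round the
  kelvin column to integers; the ≤ 0.15 K difference moves ΔG by
  ≤ 0.05 kJ/mol, inside all asserted tolerances.
- Quantities derived from published rate constants are checked at ±1%:
  published k values are rounded to two significant-ish digits, and e.g.
  ln2/0.0048 = 144.4 vs a published half-life of 143.32 shows the prints
  come from unrounded fits.

## Known limitations

- Single-phase first-order kinetics only; no Weibull/biphasic models.
- The z-value SE ignores the covariance with the intercept (pure delta
  method on the slope).
- Tukey reconstruction assumes the usual ANOVA normality/equal-variance
  conditions and uses the pooled variance even under unequal n.
- IC50s outside the tested concentration range are extrapolations of a
  straight line and should be treated as qualitative.
- The Eyring treatment assumes a transmission coefficient of 1 and a
  temperature-independent Ea across the design range.
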