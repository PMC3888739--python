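# Methods

## Model

The reduced-life-expectancy (RLE) model describes lethal toxicity under
prolonged exposure by a linear relation between the median lethal
concentration and the natural log of the median lethal time:

    LC50 = a · ln(LT50) + b,     a < 0,  b > 0,

with LC50 in µg/L and LT50 in days. The underlying mechanism statement is
written on the internal (body-residue) concentration,
ILC50 = [ln NLT − ln LT50] · d, where d is the toxicity constant (log-scale
life-expectancy reduction per unit concentration) and NLT the normal life
expectancy — the time at which half the cohort dies unexposed. Ambient and
internal concentrations are related by the bioconcentration factor
K_B = C_body / C_water at equilibrium, a fixed positive scale factor, so the
ambient-scale line has the same x-intercept: ln NLT = −b/a, d = −1/a.
The package implements only this static K_B conversion
(`internal_from_ambient`); uptake kinetics are out of scope.

Sign convention: with d = −1/a the intercept relation b = ln(NLT)/d gives
ln NLT = −b/a. Since every empirical slope is negative, this is the unique
positive root; the package uses −b/a throughout.

Assumptions worth stating: (i) linearity of LC50 in ln LT50 over the
observed range — screened, not assumed, via R²; (ii) the regression error is
additive on the concentration scale (plain OLS, no weighting, mirroring how
such tables are produced in practice); (iii) extrapolation from a 1–4 day
design to the x-intercept (hundreds to thousands of days) is meaningful,
which is the model's substantive claim, supported by agreement between
calculated and literature life expectancies.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| r2_threshold | 0.8 | — | below this a fit is flagged `low_r2` (non-linear); 3 of the 67 packaged datasets fail it |
| min_datasets | 4 | — | minimum datasets for a species-level NLT average; species below it get an `InsufficientDatasetsError` |
| r2_min | None | — | optional filter before averaging; default keeps low-R² datasets, which reproduces the published species values best |
| canonical units | µg/L, days | — | conversion once at ingest; ppm≡mg/L and ppb≡µg/L assume dilute aqueous solution (density 1 g/mL) |

Screening flags (`low_r2`, `nonneg_slope`, `constant_lc50`) never discard a
fit; only the life-expectancy operations reject non-negative slopes or
non-positive intercepts, because the x-intercept then has no life-expectancy
reading.

## Numerical choices

- **OLS** is delegated to statsmodels; two distinct points get R² = 1
  exactly; a constant response gets slope 0, R² = 0 and a `degenerate` flag
  (rather than NaN), which drives the constant-LC50 screen.
- **Through-origin regression** (reported vs calculated NLT) uses the
  uncentred total sum of squares for R², the standard no-intercept
  convention. Both day-scale and ln-scale fits are emitted; published values
  for this comparison are internally inconsistent and are not hard-coded.
- **Species averaging** is done on the log scale: arithmetic mean of per-
  dataset −b/a, then exponentiated. Averaging NLT on the day scale is
  dominated by the largest dataset and reproduces none of the published
  species values; the log-scale mean reproduces all of them within ~1.2%
  (the table's coefficients carry two significant figures, which bounds
  achievable agreement).
- **Warren's equation** c = c0 + k/t is linear in (c0, k) once time enters
  as 1/t, so the concentration-scale least-squares problem is solved exactly
  by OLS of c on 1/t; a negative unconstrained threshold is clamped to the
  boundary c0 = 0 with the conditional closed-form k = Σ(c/t)/Σ(1/t²). No
  iterative profiling is needed. Haber's k defaults to the geometric mean of
  the c·t products (least squares on the log scale with slope fixed at −1;
  symmetric in c and t, exact on ideal data); the arithmetic mean is an
  option.
- **Prediction beyond NLT** is floored at 0 µg/L and flagged rather than
  returning a negative concentration.
- **Model comparison** reports raw RSS on the concentration scale only; with
  the typical n = 4, information criteria would overreach.

## Packaged fixture

The 67 coefficient-bearing literature datasets (species, toxicant, b, a, R²,
literature NLT, source) ship as CSV inside the package. Two source rows
print no coefficients and are listed in an omissions manifest instead. One
intercept is typeset ambiguously in the source ("54,00" for methylparathion
with *Anguilla anguilla*); the fixture adopts 5400 — the reading consistent
with the published species average — and flags the entry
`ambiguous_intercept`. Obvious typesetting errors in species names were
corrected; the source's spelling "Oncorhynchus tshawytesha" is kept as
printed. Ten species have ≥4 datasets and hence a species-level average.

## Synthetic generator

`generate_series` emulates the standard acute-test design: LC50 determined
at 24/48/72/96 h (1–4 days), generated from a true line a·ln(t) + b with
additive Gaussian noise on the concentration scale — matching the fitted
model's error structure — truncated at 0 with the truncation count reported.
Lognormal (multiplicative, median-preserving) noise is an option. One
integer seed drives everything; series i uses the substream seeded by
(seed, i), so output is independent of generation order.

What it does *not* emulate: between-dataset heterogeneity within a species,
temperature effects, correlated errors across time points within a series,
or individual survival processes. Passing recovery tests therefore shows the
estimators are correct under the model, not that real series satisfy it;
the fixture-based checks carry that empirical weight.

Recovery studies in the test suite use 50–800 series per condition (200 for
the headline check: σ = 10 µg/L noise on a true line a = −100, b = 300,
i.e. ~3–6% relative noise and true ln NLT = 3), sizes at which the whole
suite runs in a few seconds while Monte-Carlo standard errors stay small
enough to detect estimator bias.

## Known limitations

- The two-stage variant of the RLE model (distinct regimes at short vs long
  times) is not implemented.
- Confidence intervals for a and b are plain t-intervals from OLS standard
  errors; with 4 points (2 df) they are wide and their empirical coverage,
  while checked in simulation, should not be over-read.
- The through-origin reported-vs-calculated comparison inherits all the
  noise in literature life-expectancy reports (the same species can differ
  several-fold between sources); its R² is expectedly low.
- ppm/ppb conversion assumes density-1 dilute solutions; brines or solvent
  mixtures would need their own conversion before ingest.
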