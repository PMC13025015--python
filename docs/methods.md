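# Methods

This note documents the statistical procedures implemented in
`iemscreen`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Panel and units

The default panel describes a 54-analyte serum screen: 25 organic
acids, 8 amino acids and 21 acylcarnitines. The 34 analytes with a
stable-isotope internal standard are quantitative (µmol/L); the other
20 — including four long-chain acylcarnitine species whose MRM
transitions were assigned empirically and that have no reference
standard — are reported as raw peak areas (a.u.). All downstream
statistics treat the two groups identically except for the below-LOD
imputation value and the absence of accuracy assessment for a.u.
analytes.

`AnalyteDef.lod` is stored in the analyte's *reporting* units. Area-
reported analytes have no published area-scale detection limit, so the
panel assigns them the fixed imputation floor of 2000 area units: the
value a censored cell receives is then also the value below which a
measurement is considered undetectable. The µmol/L detection limits
from the calibration experiments of no-IS analytes are not carried
into the panel, since they cannot be compared against a.u. cohort
values; calibration ranges are kept for record.

## Below-LOD handling

Censored cells are imputed at the LOD (quantitative) or at area 2000
(a.u.). Imputation at the LOD rather than LOD/2 or LOD/√2 is a
deliberate fidelity choice: it reproduces the reporting convention the
reference intervals and z-score models were built under. Censoring
fractions used in downstream decisions are always computed from the
pre-imputation flags, never from imputed values (imputing at the LOD
would otherwise mask censoring, since LOD-valued cells are not
strictly below the LOD).

## Reference intervals

Per analyte, on the post-imputation reference cohort:

1. **Box–Cox normalization.** The one-parameter power transform
   ((x^λ−1)/λ; ln x at λ = 0) with λ chosen by profile likelihood over
   a fixed grid [−2, 2] in steps of 0.01. Grid search instead of a
   derivative-based optimizer makes the fit bit-stable across
   platforms; the vectorized profile log-likelihood agrees with
   `scipy.stats.boxcox_llf` to ~1e-11. A two-parameter (shifted)
   variant is unidentifiable here because inputs are strictly positive
   after imputation, so it is not offered. λ is estimated once on the
   full sample and held fixed during outlier exclusion (the exclusion
   operates on already-transformed values); re-estimation after
   exclusion is available via `refit_lambda=True` and changes limits
   negligibly on clean data.
2. **Outlier exclusion at ±2.81 SD** on the transformed scale,
   iterated (up to 10 passes) until no observation is removed.
   Truncating a Gaussian at ±2.81 SD deflates the SD of the retained
   sample by a known factor √(1 − 2kφ(k)/(2Φ(k)−1)) ≈ 0.978; naive
   re-estimation compounds this shrinkage toward ≈ 0.973 at the fixed
   point, which would bias every derived limit inward (≈ 94.3% rather
   than 95% coverage, and up to ~5% relative error on the widest
   analytes). The exclusion loop therefore applies the truncated-
   Gaussian correction to the SD after each pass — the standard device
   for fitting a normal from its central portion. With the correction
   the loop converges after a single exclusion pass on clean data,
   removes ≈ 2(1−Φ(2.81)) ≈ 0.5% of observations, and leaves the SD
   estimate unbiased. The uncorrected naive behaviour remains
   available (`correct_sd=False`) for comparison.
3. **Limits** by back-transforming mean ± 1.96 SD to the original
   scale. When more than 2.5% of the reference cohort lies below the
   LOD the lower limit is not estimable from imputed data and only the
   upper limit is reported.

No age or sex partitioning is performed: the model targets a pooled
0–6-year reference population, and partitioned intervals are a known
extension, not implemented. Nonparametric and robust (Horn) interval
methods and bootstrap confidence limits on the interval endpoints are
out of scope.

## Z-scores

`z = (log10 x − μ)/σ` with μ, σ the mean and SD of the log10 reference
values of each analyte, imputed cells included, computed over all 296
reference samples without outlier truncation (whether the reference
moments should be computed after RI-style truncation is not
determined; truncation is available via the RI module if wanted).
"Valid data points" are the above-LOD reference observations: below-LOD
cells are imputed constants and carry no dispersion information. When
fewer than 100 reference observations are valid, the empirical SD is
essentially an artifact of imputation, so it is replaced by

σ := (log10(5·LOD) − μ) / 2,

i.e. calibrated so a measurement at five times the LOD scores exactly
z = 2. Only the SD is replaced; the mean stays empirical. In the fully
censored limit (all reference values at the LOD) this gives
μ = log10 LOD and σ = log10(5)/2 ≈ 0.3495, and the 5×LOD score of 2.0
is exact in floating point, which the tests assert. A reference mean
above log10(5·LOD) would make the adjusted SD non-positive and is
rejected as inconsistent input.

Patient values are imputed by the same below-LOD rule before scoring.

## Disease classification

Within each disease group (propionate-pathway disorders PA/MMA;
branched-chain disorders IVA/MCC; long-chain fatty-acid-oxidation
disorders VLCAD/CPT2/TFP) a multinomial logistic model is fitted on
the z-scores of every established marker for the group — markers are
never dropped for lack of univariate significance. The model uses a
reference-class parameterization (control class pinned to zero
coefficients), so reported coefficients and odds ratios are
interpretable as disease-vs-control effects.

Because the cohorts are small and the markers strongly diagnostic,
quasi-complete separation is expected; an unpenalized fit diverges
(infinite coefficient paths, unbounded confidence intervals). The
default L2 penalty of 0.01 on non-intercept coefficients makes the
optimum finite, unique (strictly convex objective) and reproducible
while leaving the decision boundary essentially unchanged. The penalty
is configurable, and 0 is allowed with explicit divergence detection.
Optimization is L-BFGS with an analytic gradient from zero
initialization; on small toys the optimum matches a brute-force grid
search of the same penalized likelihood, and predictions agree with an
independently parameterized solver. Odds ratios with |β| > ln 999 are
flagged as beyond the reportable range. Ties in predicted probability
are broken by declared class order.

Only the five-marker panel of the PA/MMA group is fixed by its source;
the group-B and group-C marker lists are reconstructions from the
marker–disease correspondences of the respective disorders and ship as
editable JSON defaults.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not serum biochemistry:

* Per-analyte independent log-normals. Two-sided reference limits
  [L, U] are inverted exactly: μ = (log₁₀L + log₁₀U)/2,
  σ = (log₁₀U − log₁₀L)/(2·1.96). For upper-only analytes the healthy
  distribution is under-determined by the published limits, so it is
  anchored at the LOD: σ = 0.25 log10 units and μ chosen so that 20%
  of healthy mass falls below the LOD — a deliberate choice above the
  2.5% upper-only reporting threshold.
* Disease cases shift each diagnostic marker by `z_shift` healthy-SD
  units on the log10 scale (default 6 for primary, |4| for secondary
  markers; negative for depletion markers such as citrulline in OTC
  deficiency or tyrosine in PKU). Within-disease variance equals
  healthy variance. Effect sizes for real patients are not published;
  these defaults are conventions chosen so that simulated cases show
  unambiguous signatures (mean marker z ≫ 3), and they are editable
  per run.
* No correlations between analytes, no age/sex structure, no
  biochemical stoichiometry between pathway members, and no analytical
  batch effects.

Consequently, passing tests establish that the *statistical machinery*
is correct (parameter recovery, coverage, exclusion rates,
classification under the assumed model) — not that the pipeline's
clinical performance on real sera matches, where correlated analytes,
heavier tails and treatment effects will matter.

Simulation sizes follow the study design they emulate: 296 reference
samples, 341 control profiles plus 18 PA and 25 MMA cases for the
group-A classification experiment. Engine-recovery properties are
checked at n = 10 000 per analyte (limits within 5% relative of the
generating values; ≈95% ± 1% coverage of 100 000 fresh draws), sizes
at which Monte-Carlo noise is well below the asserted tolerances.

## Method validation engine

Linearity is an unweighted OLS of response (area ratio for IS-bearing
analytes, raw area otherwise) against nominal concentration over a
two-fold dilution series; weighting (e.g. 1/x) is deliberately not the
default since the calibration model is specified unweighted, but a
level mask allows per-analyte exclusion of top/bottom calibrators (the
published per-analyte "calibration points" of 8 or 9 imply such
drops, with no stated auto-selection rule — so none is invented).
LOD/LOQ consume an S/N column (chromatogram processing is out of
scope) and take the lowest concentration whose S/N exceeds 3 (LOD) or
10 (LOQ) with all higher levels also passing, which makes LOQ ≥ LOD
structural. Between-run CV pools all inter-day replicates as one
sample (n = 5 per condition; no nesting is described, so none is
modelled). Accuracy uses mean recovery against nominal; analytes
without an IS get no accuracy figures.

## Numerical conventions

* Seeds: every stochastic stage takes an explicit seed; per-stage
  sub-seeds are derived through `numpy.random.SeedSequence` and kept
  below 2³¹. Identical inputs and seeds reproduce outputs bit for bit.
* Degenerate inputs fail loudly: constant samples (Box–Cox SD 0),
  all-excluded outlier passes, non-positive values before log
  transforms, IS failures (zero IS area), duplicate markers
  (collinear by construction), labels outside the declared classes.
* Report CSVs round to 4 significant figures; JSON artifacts keep full
  precision. Measurement CSVs round-trip exactly (values are written
  with `repr` and parsed with Python's correctly-rounded float
  parser); censored cells serialize as `"<LOD"` once imputed.
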