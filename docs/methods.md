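# Methods

This note documents the statistical procedures implemented in `vegtrend`,
the choices made where conventions diverge, and what the synthetic fixtures
do and do not establish about real data.

## Mann–Kendall test and slope estimators

For an annual series x₁…xₙ the test statistic is the signed pair count
S = Σᵢ>ⱼ sign(xᵢ − xⱼ) with variance

  Var(S) = [n(n−1)(2n+5) − Σₖ tₖ(tₖ−1)(2tₖ+5)] / 18,

the sum running over tied groups of size tₖ. The standard normal statistic
Z applies the ±1 continuity correction ((S−1)/√Var for S > 0, (S+1)/√Var
for S < 0, 0 at S = 0) and is referred two-sided to N(0,1). Significance is
flagged at 0.05 ("\*") and 0.01 ("\*\*"). Missing values are a hard error:
the intended inputs are complete annual aggregates, and silent deletion
would change the meaning of n in the variance.

The Theil–Sen slope is the median of all C(n,2) pairwise slopes
(xᵢ−xⱼ)/(i−j), computed via `scipy.stats.theilslopes`; an OLS slope is
reported alongside for comparison. Decadal rates in reports are exactly
10× the annual Sen slope — the "/10a" convention of regional NDVI studies.
Sen slope and S are invariant under adding a constant; Z is invariant under
any strictly increasing transform; the Sen slope scales linearly under
positive rescaling. These invariances are enforced as property tests.

Minimum series length is 4 for the test (below that the normal
approximation is meaningless) and 10 for the sequential variant.

## Sequential change-point detection (UF/UB)

The progressive statistic is computed in its signed-pair-count form
UFₖ = Sₖ/√(k(k−1)(2k+5)/18), where Sₖ is the MK statistic of the first k
points; the retrograde curve UB is the negated progressive statistic of the
reversed series, re-reversed. For distinct values this is algebraically
identical to the classical exceedance-count formulation
(Tₖ − k(k−1)/4)/√(k(k−1)(2k+5)/72), but it remains centred (E[Sₖ] = 0)
under ties, where the exceedance form drifts negative on constant runs.

A change point is reported at the later year of a sign change of UF − UB
when either endpoint of the crossing lies inside the ±z₁₋α/₂ band
(α = 0.05 by default). Two limitations are inherent to the method and
documented by tests rather than hidden:

- **Localization under noise.** MK statistics are rank-based and therefore
  scale-free: for a step between two flat regimes, i.i.d. noise of *any*
  standard deviation randomizes the within-regime ranks, so crossing
  precision does not improve as noise shrinks. Measured on a unit step at
  n = 38: the noiseless crossing is exact; with any nonzero i.i.d. noise
  ~60% of crossings fall within ±1 year (symmetric dispersion, median
  absolute error 1 year).
- **Trend contamination.** For a globally monotone series UF and UB cross
  mid-series regardless of any embedded break; the method presumes a
  trendless pre-break regime.

## Full-order partial correlation

For a panel of jointly observed variables, the partial correlation of the
response with covariate v given all other covariates is taken from the
precision matrix P (inverse of the full correlation matrix):
r = −P₍ᵢⱼ₎/√(P₍ᵢᵢ₎P₍ⱼⱼ₎). This equals the correlation of the residuals
after regressing both variables on the controls; the equivalence is tested
to 1e−10 against that oracle and against `pingouin.partial_corr`.

Degenerate panels are resolved by the residual definition: a perfectly
collinear response/covariate pair yields ±1; a response fully explained by
the controls alone yields 0 for the remaining covariates (nothing left to
correlate); collinearity among controls is an error naming the offending
pair, since the coefficient is then 0/0.

Significance uses t = r·√((n−p−2)/(1−r²)) with n−p−2 degrees of freedom,
where p is the number of controlled covariates. An alternative statistic
t = r·√((n−p−1)/(1+r²)) circulates in parts of the applied literature; it
is provided as `mode="as_printed"` for comparability but is not the
default, because it is not monotone-equivalent to the standard test (the
(1+r²) denominator shrinks the statistic as |r| grows). Its p-value also
uses n−p−2 degrees of freedom, the only defensible choice. Windowed
analysis requires at least three more years than covariates per window.

## GM(1,1) grey model

The raw positive series x⁽⁰⁾ is accumulated (AGO) to x⁽¹⁾, the whitened
equation dx⁽¹⁾/dt + αx⁽¹⁾ = β is fitted by least squares on
x⁽⁰⁾(k) = −α·z⁽¹⁾(k) + β with z⁽¹⁾(k) = ½(x⁽¹⁾(k)+x⁽¹⁾(k−1)), and
forecasts come from the closed form
X⁽¹⁾(k+1) = (x⁽⁰⁾(1) − β/α)e^(−αk) + β/α, inverted by first differencing
with x̂⁽⁰⁾(1) ≡ x⁽⁰⁾(1). At |α| < 1e−12 the linear limit
X⁽¹⁾(k+1) = x⁽⁰⁾(1) + βk is used, so constant series forecast exactly.

A numerical point worth knowing: on geometric growth A·qᵏ⁻¹ the trapezoid
estimator returns α̂ = −2(q−1)/(q+1), the bilinear approximant of −ln q,
not −ln q itself. The model therefore reproduces a q = 1.01, n = 20
geometric series to ~1e−5 relative error (a constant amplitude offset from
the (1−e^α) differencing factor plus an 8e−8-per-step drift), while the
*ratio* of successive forecasts matches q to ~1e−7. Exact reproduction
would require solving the grey difference equation recursively instead of
the exponential closed form; the closed form is kept because it is the
standard published prediction equation.

Inputs must be strictly positive and n ≥ 4. The class-ratio admissibility
band σ(k) = x⁽⁰⁾(k−1)/x⁽⁰⁾(k) ∈ (e^(−2/(n+1)), e^(2/(n+1))) is checked and
violations emit a warning, not an error — short noisy ecological series
frequently brush the band, and the diagnostics below are the real gate.

Diagnostics:

- **Residual table** — difference = predicted − measured and
  similarity % = 100·(1 − |difference|/measured), displayed rounded half
  away from zero at 2 d.p., full precision retained.
- **Grey relational grade** — ξ(k) = (Δmin + ρΔmax)/(Δ(k) + ρΔmax) on the
  absolute residuals with resolution coefficient ρ = 0.5; R is the
  arithmetic mean of ξ over all compared points (the all-zero-residual case
  takes ξ ≡ 1 by the 0/0 convention). R > 0.5 is the conventional pass.
- **Posterior difference ratio** — C = sd(residual)/sd(measured) with
  sample (ddof = 1) standard deviations, graded excellent/good/qualified/
  unqualified at 0.35/0.5/0.65. Small C is good: on series with no
  structure beyond noise, C concentrates near 1.

The only "revision" offered beyond the plain model is `rolling_gm11`, a
metabolic variant that refits on a trailing window and records one-step
forecasts, useful when the growth rate drifts.

## Synthetic generators

`gen_piecewise_series` produces value-continuous piecewise-linear series:
the first year takes the intercept and each subsequent year advances by the
slope of the segment containing it. The default fixture spans 1981–2018
with segment rates +0.0016/yr (1981–1997), −0.0025/yr (1998–2009) and
+0.0033/yr (2010–2018) from an intercept of 0.2876 — the staged trajectory
the package's reports are shaped around. Noise is stationary AR(1) Gaussian
(innovation sd σ, lag-1 coefficient φ, stationary initial draw); annual
ecological series are autocorrelated, and φ = 0 recovers i.i.d. noise. The
pipeline default σ = 0.01, φ = 0.2 gives a realistic signal-to-noise for
area-mean NDVI.

`gen_covariate_panel` draws i.i.d. years from N(0, P⁻¹) for a prescribed
precision matrix P, making −Pᵢⱼ/√(PᵢᵢPⱼⱼ) the known ground-truth partial
correlation; recovery within ±0.05 at n = 10⁴ is part of the test suite.
`gen_grid_stack` builds linear-plus-noise pixel series with a per-pixel
slope field and propagating nodata mask.

What the fixtures do *not* emulate: spatial autocorrelation between pixels,
sensor artifacts or archive merging, calendar effects, and non-Gaussian
noise. Passing tests demonstrate estimator correctness and calibration
under the stated error model, not robustness to those features.

## Problem sizes and numerics

Simulation-based checks use sizes chosen to pin the statistics tightly at
interactive runtimes: 2000 replicates for the null rejection rate at
n = 38 (binomial sd ≈ 0.005 around 0.05), 500 random series up to n = 200
for the brute-force oracle, 200 replicates for change-point localization,
and n = 10⁴ panels for partial-correlation recovery. Grid I/O stores
nodata as −9999 in NetCDF (scipy backend, NetCDF3) or per-year TIFF
directories; a geotransform, when present, travels as a plain attribute.
CSV readers normalize the Unicode minus to ASCII and reject gaps,
duplicates and non-numeric cells rather than repairing them.
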