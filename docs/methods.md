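# Methods

## What the package computes

The package evaluates an ensemble of model datasets against one or more
observation-like datasets of annual gridded NPP and its drivers (SST,
CHL, MLD), in four stages: trend estimation, jackknifed per-pixel
multiple linear regression, biome-stratified distribution comparison by
Earth mover's distance, and Z-score ranking.  All stages operate on
mean-normalised series — each pixel's series divided by its mean — so
coefficients and trends are dimensionless fractional responses,
comparable across pixels, datasets and physical units.

## Trend estimation

Per pixel, a series is fitted only if at least half its years are
present.  The series values are tested for normality
(D'Agostino–Pearson); if not rejected at α = 0.05 the trend is a robust
Huber regression on year with ε = 1.35 (the tuning giving 95 % Gaussian
efficiency), implemented as iteratively reweighted least squares; points
whose final robustness weight falls below 1 count as removed, and if
fewer than half the years survive the pixel is dropped.  If normality is
rejected, the Mann–Kendall test (tie-corrected variance, continuity
correction) supplies the p-value and the Theil–Sen estimator the slope.
A perfect linear series has zero robust scale, where the IRLS iteration
is undefined; the Huber solution there is the OLS solution and is
returned directly.  Constant series return slope 0, p = 1.

Two calibration caveats, both measured by the test suite:

- The normality gate has limited power at n = 26. It detects Pareto- or
  Cauchy-type tails in ≳90 % of cases but symmetric t(3)-type tails in
  only about half; mildly heavy-tailed pixels will often be fitted by
  the Huber path (which is itself robust, so the practical cost is
  small).  The routing check uses Pareto(α = 1) noise, whose tail
  weight and skewness the test detects reliably at this length.
- Normality is tested on the series values, not on detrended residuals
  (`pixel_trend` follows the stated procedure literally); a strong
  trend with Gaussian noise can therefore occasionally be routed to the
  rank-based path.  This is switchable in principle by detrending before
  the gate; the default follows the procedure as specified.

Regional trends are OLS on the cos(latitude)-weighted,
mean-normalised spatial mean, ×100 into % yr⁻¹ (scale-invariant by
construction).  ΔNPP integrates the area-weighted change between two
reference windows over the ocean area, converting at 12.011 g C mol⁻¹, a
365-day year and 1 Pg = 10¹⁵ g (all configurable).

## Driver regressions

Per pixel, OLS with intercept of normalised NPP on normalised SST, CHL
and MLD over the retained window.  No fit is attempted if any series has
a missing year or any driver variance is ≤ 10⁻¹⁰ (the "~0" rule on the
normalised scale).  Inference is Newey–West HAC with Bartlett kernel at
lag ⌊4·(T/100)^(2/9)⌋ (lag 2 at T = 26, lag 4 at T = 165), a
degrees-of-freedom correction, and a Student-t reference distribution —
the t reference is a deliberate small-sample choice.  A coefficient
survives to the maps only when its own p ≤ α **and** the model F-test
p ≤ α (the stricter of the two readings of "not significant"; each gate
can be disabled).  Zero-residual (noise-free) fits have undefined
sampling inference; they are flagged `degenerate` and treated as
significant with p = 0 so that exact-recovery analyses are not masked.

Known limitation, quantified by the calibration test in the acceptance
suite: with strongly autocorrelated residuals (AR(1) φ = 0.6) at T = 26,
the rule-of-thumb lag truncates the Bartlett kernel far short of the
residual memory, so HAC t-tests over-reject null drivers (observed
rejection well above the nominal 5 %) and 95 % intervals under-cover
(observed ≈ 83 %).  This is a property of the estimator at this series
length, not of the implementation: the kernel at lag 2 recovers only
about half the long-run variance of AR(0.6) noise, implying a t-statistic
inflation of ≈ 1.4.  A second small-sample effect runs the other way:
because each regressor's scores sum to zero under OLS, their sample
autocovariances are biased negative at small T, and the HAC standard
error then sits *below* the classical OLS one on average at T = 26 even
under positive residual autocorrelation; the HAC ≥ OLS ordering holds at
the full model-era span T = 165.  Users fitting short windows should
treat per-pixel significance as approximate; the distribution comparison
downstream is less sensitive because it pools thousands of pixels.

Jackknifing applies to the observation datasets only: every contiguous
window of 20 of the 26 years (7 assessments).  Model datasets are fitted
once over their full span.

## Distribution comparison and ranking

Within each biome, the significant coefficients of a driver from the
model and from the observations form two samples; each is fenced to
[Q1 − 3·IQR, Q3 + 3·IQR] (quartiles by linear interpolation between
order statistics — the convention is fixed for reproducibility; samples
under 4 values pass unfiltered), and the first Wasserstein distance
between the fenced samples is computed.  Biome distances are averaged
with areal-proportion weights; biomes empty on either side are dropped
and the weights renormalised.  Per model, the three driver distances
give a mean and a sample (ddof = 1) standard deviation; both are
standardised across the ensemble as z = (x − μ)/σ (a degenerate
ensemble, σ = 0, yields z = 0; spreads below 10⁻¹² of the EMD magnitude
are snapped to zero first, since `std` of identical floats returns
rounding noise that standardisation would otherwise amplify).  The two
Z-scores are averaged with equal weight and models ranked ascending;
ties break by lower EMD mean, then model identifier.  Across
assessments, the ΔNPP of the model occupying each rank is reported as
mean ± sd, with the sd absent when a single model holds that rank in
every assessment.

## NPP algorithm skeletons

The six formula structures are implemented with pluggable inner
parameterizations on `AlgorithmParams`:

- **VGPM**: NPP = Chl · P^B_opt(SST) · DL · f(PAR) · Z_eu, with
  f(PAR) = 0.66125·PAR/(PAR + 4.1); P^B_opt is either the Eppley
  exponential 1.54·10^(0.0275·T − 0.07) or the published 7th-order
  polynomial clamped to 1.13 below −1 °C and 4.00 above 28.5 °C.  The
  polynomial is non-monotone with an interior optimum; on warming water
  above that optimum the two variants diverge in trend sign, which is
  the structural behaviour the warming-scene test asserts.
- **CbPM**: phytoplankton carbon C_ph = 13000·(b_bp(443) − 0.00035)
  mg C m⁻³ (clamped at zero below the offset, logged).  The growth-rate
  mapping μ(Chl:C, I_g) ≤ μ_max (defaults μ_max = 2 d⁻¹,
  Chl:C_max(I_g) = 0.022 + 0.023·e^(−3I_g), saturating light response,
  I_g the mixed-layer-midpoint hourly irradiance) is a documented
  simplification of the full carbon-based physiology and is replaceable.
  The depth-resolved variant integrates C_ph(z)·μ(z) to Z_eu by
  trapezoid on a 1 m grid with Kd(490)-attenuated light (and an
  e-folding carbon decline below the nitracline when given).
- **AbPM**: NPP = f(a_ph(443), K_d(490), Z_eu, PAR) with f pluggable;
  the default is a documented simplified absorption model (photons
  absorbed by phytoplankton over the euphotic column times a fixed
  carbon yield ψ = 600 mg C per mol photons), not a transcription of the
  original inner function.
- **CAFE**: NPP = Q_PAR · Φ^max_μ · tanh(E_k/PAR), implemented exactly
  as the skeleton is printed.  Note this form *decreases* with PAR at
  fixed E_k — the full source model's light response enters the other
  way up — so it should be read as a structural placeholder; Q_PAR
  defaults to a carbon-equivalent absorbed-energy term derived from
  a_ph, K_d, Z_eu and PAR, and PAR = 0 takes the saturating tanh → 1
  limit (logged).

All variants guarantee non-negative NPP and zero NPP at zero biomass
proxy.

## Mixed-layer depth

Density profiles come from a pluggable equation of state — the default
is the one-atmosphere International Equation of State of Seawater
(Millero & Poisson 1981 polynomial in T and S); a linear stub is used in
tests.  MLD is the first depth at or below the 10 m reference where
density exceeds the reference density by 0.03 kg m⁻³, interpolated
linearly in density between bracketing levels; profiles that never cross
return the deepest level flagged unresolved.

## The synthetic generator

Each driver's normalised series is 1 + γ·(t − t̄) + c(t) + ε(t): a
per-pixel linear trend γ (defaults ~0.1–0.2 % yr⁻¹ in magnitude, the
satellite-era scale), a small deterministic driver-specific cycle c(t)
(amplitude 0.02, periods 2.7–5.2 yr, demeaned exactly over the series —
an ENSO-like mode that also keeps the regression design full-rank at
zero noise), and stationary AR(1) noise ε (marginal sd 0.03, lag-1
autocorrelation φ = 0.3 by default), initialised from its stationary
distribution so no burn-in is needed.  Normalised NPP is
β₀ + β_sst·x_sst + β_chl·x_chl + β_mld·x_mld + ε with coefficient fields
whose zonal structure mirrors driver regressions of satellite NPP
(negative SST coefficients at low latitudes, positive CHL everywhere,
small negative MLD poleward, magnitudes roughly halving from SST to CHL
to MLD).  Physical fields are pure scalings of the normalised ones
(SST base 18 °C, CHL 0.25 mg m⁻³, MLD 60 m, NPP scale
500 mg C m⁻² d⁻¹), so downstream mean-normalisation cancels units
exactly and the zero-noise coefficient recovery is exact to machine
precision.

The pseudo-ensemble (15 members by default) shifts each member's
coefficient fields by a uniform per-driver δ (Gaussian, sd 0.15) and
prescribes a ΔNPP scalar per member (centred on a decline of 0.76 Pg C
yr⁻¹ with spread 3.44, correlated with the member's shift magnitude so
the ranking read-out carries signal).  Biomes are contiguous latitude
bands with cos(latitude) areal proportions — the ranking mathematics
needs only labels and weights, not realistic province geometry.

What the generator does **not** emulate: sub-annual compositing and
cloud-gap structure (only a missing-at-random mask is available),
spatially correlated noise, scenario forcing, non-linear NPP–driver
relationships, and any noise spectrum beyond AR(1) — the AR(1) choice is
an assumption, since the noise spectrum of real NPP fields is not well
characterised.  Passing tests therefore demonstrate that the pipeline
recovers what it is designed to recover under these idealised
conditions, not that the method is well calibrated on real fields (see
the HAC caveat above, which points the other way).

## Problem sizes and numerical choices

The default configuration is a 36 × 18-cell global grid over 26 years
with 6 observation sources, 15 pseudo-models and 6 biomes — the package's
desk-scale stand-in for the satellite-era analysis; the full pipeline at
these sizes runs in about a minute on one core, and the test suite uses
smaller grids (≈ 80–520 pixels).  Zero-mean normalisation sentinel:
|mean| ≤ 10⁻¹² × max|value|.  Driver-variance skip: 10⁻¹⁰.  Quartiles:
linear interpolation.  Standard deviations: sample (ddof = 1) throughout
the ranking.  Seeds: every stochastic object derives its stream from a
single integer seed via seed sequences; identical configuration and seed
reproduce every artifact bit-for-bit.
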