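# Methods

This note documents the models implemented in `ringphys`, the choices made
where the procedure was genuinely open, the synthetic-data generator's
assumptions, and the limits of what the test suite demonstrates.

## Isotope physiology

Wood δ¹³C (‰ vs VPDB) is converted to foliage δ¹³C with the empirical
linear relation δ_foliage = 1.0523·δ_wood − 0.205, then expressed as
discrimination against atmospheric CO₂ in the standard
Farquhar–Ehleringer form

    Δ¹³C = (δ_air − δ_foliage) / (1 + δ_foliage/1000).

Intercellular CO₂ follows the simple (linear) discrimination model
Ci = Ca·(Δ − a)/(b − a) with a = 4.4‰ (diffusion through stomata) and
b = 27‰ (carboxylation); intrinsic water-use efficiency is
iWUE = (Ca − Ci)·0.625, the constant being the CO₂/H₂O diffusivity ratio
under A = (Ca − Ci)·g_c. These forms have the correct boundary behaviour:
Δ = a gives Ci = 0 and Δ = b gives Ci = Ca. No mesophyll-conductance or
post-photosynthetic fractionation terms are included, and no juvenile-effect
correction is applied (the analysis period post-dates recruitment by
decades).

For a multi-year wood segment the atmospheric δ¹³C_air and Ca are linearly
interpolated at the segment's arithmetic midpoint year. Averaging the annual
values across the segment instead (`atmosphere_at="mean"`) differs
negligibly for ≤5-year segments on a near-linear record; both are exposed.
Extrapolation beyond the tabulated atmospheric record is an error, never a
silent extension.

Δ values outside [a, b] (possible under measurement noise) produce Ci
outside [0, Ca]; these are logged, not rejected, so that period means remain
unbiased.

## Biomass reconstruction

Per-year under-bark radius is the cumulative ring-width sum plus the pith
offset; over-bark diameter applies a multiplicative factor (default 1.096)
representing bark and shrinkage, of the kind calibrated by zero-intercept
least squares of tape-measured final diameters on reconstructed ones
(`bark_factor_calibration`). Cambial age at the coring height uses a pith
date estimated as

    pith_year = first_year − round(pith_offset / mean width of the five
                innermost rings) − 10,

the 10 added years accounting for growth from stump to coring height; age in
year t is t − pith_year + 1 (inclusive count). The `stump_age_years`
parameter exposes the offset because the two conventions in circulation
(10 added years vs an 11-year constant inside the age formula) differ by
one year; the inclusive-count form used here reconciles them.

Height (m) is a catchment-specific polynomial in diameter (cubic for
Čertovo, quadratic for Plešné); crown length uses a single power law for
both catchments (its influence on total biomass is minor). Five biomass
components are log-linear models in ln(diameter/10), ln(height), ln(age)
and ln(crown length), each with a multiplicative correction factor applied
to the whole linear predictor exactly as the source models are printed —
the factors resemble log-bias corrections, which are conventionally applied
differently, but fidelity to the printed form wins. Diameter is mm
end-to-end; the /10 inside the biomass predictors converts to cm
internally. Total biomass is the component sum and the annual increment its
first difference; negative increments (possible when age terms dominate in
a zero-growth year) are logged, never dropped.

The whole chain is deterministic: identical inputs give bit-identical
outputs.

## Detrending and chronology statistics

Inter-annual variability uses mean sensitivity,
mean of 2|xᵢ − xᵢ₋₁|/(xᵢ + xᵢ₋₁), bounded in [0, 2] and invariant to
positive rescaling; zero-sum pairs are skipped with a warning.
Persistence is the lag-1 Pearson autocorrelation.

The adaptive power transform estimates p = 1 − m, with m the pooled
least-squares slope of log₁₀(IQR) on log₁₀(median) over non-overlapping
10-year segments (short tail segments dropped; p clipped to [0.05, 1]).
The regression orientation (IQR as response) is the one under which
p = 1 − m reproduces the classic variance-stabilizing rule — homoscedastic
series give p ≈ 1 (no transform), spread proportional to level pushes p to
the near-log lower clip. Negative values entering the transform are clipped
to zero with a warning.

The smoothing spline is implemented as the discrete penalized
(second-difference / Whittaker) smoother (I + λDᵀD)ŷ = y, the discrete
analogue of the cubic smoothing spline on evenly spaced years. λ is chosen
numerically (bisection) from the analytic amplitude response
H(f) = 1/(1 + 16λ sin⁴(πf)) so that a sinusoid of the design wavelength
(default 30 years) is attenuated to the design fraction (default 50%) —
the standard frequency-response criterion. The response is monotone in
frequency, and the choice is reproducible for any series length ≥ half the
wavelength. Detrending is by subtraction (residual = transformed − spline),
not division.

Climate series are spline-detrended with p = 1, i.e. without the power
transform: temperature and PDSI can be ≤ 0, where a power transform is
undefined. The adaptive power is estimated from biomass-increment series by
default; ring widths can be supplied instead.

## Growth–climate correlations

Monthly series are aggregated into four season windows — growing-season
temperature (May–Sep, mean), early-season cloud cover (May–Jul, mean),
previous-year late-growing-season precipitation (Jul–Sep, sum) and
previous-September PDSI — with previous-year months attached to the ring
year they influence. A preliminary screen correlates the mean detrended
chronology against all 24 candidate months (current + previous year) over
1901–2007 using Spearman ρ with two-sided t-approximate p-values and no
multiplicity correction; it is exploratory and flagged as such. Final
correlations are per tree × season × period (minimum 5 overlapping years,
otherwise flagged missing); running correlations use a centered 31-year
window by default (the window length is a package choice; only oddness and
a ≥11-year floor are enforced).

## Period models

One value per tree × period is formed by plain means for annual series, by
segment-length-weighted means for multi-year isotope segments (weight =
years of overlap with the period), and by within-period mean sensitivity
for the variability response. The model is a random-intercept linear mixed
model with candidate fixed structures {intercept, period,
period + catchment, period × catchment} (± a covariate when supplied),
compared by ML AIC with k = fixed effects + 2 (random-intercept and
residual variances), then refit by REML for reported estimates. Reference
levels: the earliest period and the Čertovo catchment. Singular or
non-converging candidates are skipped with a warning (the optimizer itself
falls back lbfgs → bfgs → powell before a candidate is abandoned).

Pairwise period comparisons use model-based marginal means (averaging the
catchment dummy at 0.5 and covariates at their mean) and a single-step
max-|Z| adjustment; the joint null distribution of the contrast statistics
is evaluated by fixed-seed Monte Carlo (200 000 draws), making the adjusted
p-values deterministic to ~2×10⁻³. Letters come from the insert-and-absorb
compact-letter-display algorithm, which guarantees that exactly the
significant pairs share no letter. Pseudo-R² follows Nakagawa–Schielzeth:
R²m = var(Xβ)/(var(Xβ) + σ²_tree + σ²_resid), R²c adds σ²_tree to the
numerator. Degrees of freedom use the normal approximation, adequate at the
tree counts involved (≥ 25 groups).

`CoefficientTable` holds a fitted (or transcribed) model's fixed effects
under canonical term names and performs the report arithmetic: a period ×
catchment prediction is the sum of intercept and applicable terms, and
percent change is (target − baseline)/baseline × 100, rounded to the
nearest integer (absolute differences to one decimal) to match how such
contrasts are conventionally quoted. A term absent from a best model is
treated as absent — predictions that require it raise — not as zero.
Transcribed tables may use decimal commas; the parser accepts both comma
and point. For "recent increase" statements the baseline is the 1971–1989
prediction; both baselines are emitted with labels where ambiguous.

The increment–discrimination model regresses biomass increment on Δ¹³C,
period and their interaction with a random tree intercept; per-period
slopes are the Δ¹³C coefficient plus the period's interaction term.

## Synthetic data generator

The generator emulates the statistical structure of the study inputs; its
defaults are the study conditions and are not tuned per run.

* **Atmosphere**: deterministic logistic Ca(t) = 295.642 +
  163.986/(1 + exp(−(t − 2006.401)/25.532)), rising from ≈296 ppm (1850) to
  ≈385 ppm (2011) with period means ≈339 ppm (1971–1989) and ≈381 ppm
  (2006–2011); δ¹³C_air declines linearly in Ca from −6.4 to −8.3‰. The
  four logistic constants were solved once by least squares against those
  four anchor values and frozen.
* **Climate**: monthly temperature = 4 °C annual mean + 8.5 °C seasonal
  cosine + 0.008 °C yr⁻¹ trend + year effects (SD 0.8 °C) + monthly noise
  (SD 1.5 °C); precipitation gamma-distributed (monthly mean 105 mm, shape
  4, ≈1260 mm yr⁻¹); cloud cover anti-correlated with temperature
  anomalies, clipped to [0, 100]; PDSI an AR(1) (φ = 0.7) of standardized
  precipitation anomalies.
* **Ring widths** (105 trees per catchment): width = (2.5·e^(−age/80) +
  0.5) mm × exp(0.12·z_T + ε + b), with z_T the standardized May–Sep
  temperature, ε an AR(1) (φ = 0.85, innovation SD 0.25) and b ~ N(0, 0.3)
  a tree-level growth intercept; pith offsets uniform on [0, 10] mm,
  recruitment uniform on 1780–1860. These settings put the realized mean
  sensitivity near 0.23 and the lag-1 autocorrelation near 0.85, inside the
  0.15–0.30 and 0.75–0.92 brackets typical of such chronologies.
* **Isotopes** (25 + 6 trees): per-segment Δ¹³C = 19.635 + period effect
  (−1.876 / −0.696 / −0.480‰ for the pollution and two recovery periods)
  + tree intercept (SD 0.57) + segment noise (SD 0.7), inverted through the
  discrimination model and the foliage/wood relation at the segment
  midpoint. The two SDs were chosen so the fitted model's conditional
  pseudo-R² lands near 0.87, matching the variance partition the effect
  magnitudes imply. Segment lengths are 1–5 years and are cut at period
  boundaries so no segment straddles two defined periods — this keeps the
  configured effects exactly identifiable by the overlap-weighted period
  means, at the cost of a segmentation regularity real cores need not have.

All generators are deterministic given a seed. What passing tests show is
that the *machinery* is correct under the generator's assumptions
(multiplicative AR(1) growth, additive period effects on the Δ¹³C scale,
Gaussian noise); they cannot show that real wood isotope series satisfy
those assumptions, and the generator deliberately omits cross-dating error,
missing rings beyond width 0, within-segment trends, and disturbance or
competition pulses.

## Numerical choices and degenerate inputs

* Tucson (.rwl) dialect: 8-character id field, decade-aligned rows,
  0.01 mm units, 999 (or −9999) terminator; zero widths are legal missing
  rings; round-trips are lossless at 0.01 mm.
* Atmospheric interpolation is linear and refuses extrapolation.
* Sensitivity skips zero-sum pairs (warning) and errors only when all pairs
  degenerate; autocorrelation of a constant series is NaN with a warning.
* Power regression drops non-positive-median or zero-IQR segments.
* The mixed-model AIC uses ML log-likelihoods only; REML likelihoods are
  never compared across fixed structures.
* Problem sizes in the validation suite (200 mixed-model replicates, 2000
  Spearman null replicates, 300-point spline oracle) were chosen so each
  check resolves its tolerance comfortably; they are package choices, not
  statements about the original sample sizes.

## Known limitations

* The mixed models assume homoscedastic residuals across periods, while
  period means aggregate different numbers of years/segments; at the
  variance components used this is a second-order effect (coverage stays at
  or above nominal in the recovery suite).
* Tukey adjustment uses the normal rather than t reference; with ≥25 trees
  the difference is small but p-values near the threshold may be slightly
  liberal.
* The crown-length model is shared across catchments and the bark factor is
  pooled; site-specific refits would need the underlying calibration data.
* PDSI is an input variable; no water-balance model is implemented.
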