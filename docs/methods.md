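# Methods

## The measurement model

All analysis operates on reflectance signatures ρ(λ): unitless fractions
(percent/100) on a strictly increasing wavelength grid. Raw spectrometer
counts are calibrated by the standard two-point rule
ρ = (raw − dark)/(white − dark) against a white reference (100 %) and a
dark/blocked reading (0 %). The working range is 400–900 nm (leaf
spectrometers are unreliable in the UV and beyond the NIR shoulder), and a
~1 nm native grid is coarsened to 3 nm by averaging non-overlapping
3-channel windows anchored at the first retained wavelength, the trailing
partial window averaged as-is. Ten readings per leaf/plot are averaged
before any index math; the reader auto-detects percent-scaled CSV input
(any value > 1.5) and divides by 100 unless told otherwise.

Broad bands are means over the named closed ranges violet 400–451, blue
454–496, green 499–517, yellow 574–589, orange 592–619, red 622–748,
red-edge 691–730 and NIR 751–997 nm, each intersected with the available
grid. Two quirks of the tabulated convention are kept deliberately: the red
range overlaps red-edge, and violet is implemented as the 400–451 nm mean
(its tabulated entry prints a ρ400/ρ451 ratio that contradicts the prose
definition of broad bands as range averages; the average is the consistent
reading). Narrow-band lookups resolve the nearest channel within a 2 nm
tolerance (half the 3-nm spacing, rounded up) with ties broken to the lower
wavelength, so formulas citing e.g. ρ625 work on both 1-nm and 3-nm grids.

## Indices and wax prediction

The three index registries transcribe their published formulas literally,
including forms that deviate from naming conventions (NDWI as a plain
ratio, RGRI as Red − Green, MSR with Red in the numerator). Ambiguities
resolved: EWI-10 squares the whole normalized difference — the only reading
consistent with its large positive intercept (4.92) and negative slope
(−1.03) on a quantity otherwise confined to tiny positive values; EWI-5 is
the single band ρ676; EWI-8 is the printed ρ694/ρ625 even though its
near-zero negative slope suggests a transcription oddity upstream.

Inverse prediction follows the classical calibration-curve logic: the line
index = a + B·EW is fitted with EW (the chemically assayed truth) as
regressor, and prediction inverts it, EW = (index − a)/B. The (a, B) pairs
of the built-in EWI calibrations are interpreted in this direction; the
alternative direction would produce predictions an order of magnitude below
the trait's observed range. Predictions are never clamped: negative values
and EWI-1 predictions above its 6 mg/dm² saturation range carry a
`SaturationWarning` so downstream QC can see them.

The EWM band-linear models predict EW = β₀ + Σ β_λ ρ_λ on the fraction
scale — coefficient magnitudes near 100 are only dimensionally plausible
there. The published coefficient digits are concatenated in the source
table; the parse frozen in `prediction.py` is pinned by three independent
cross-checks: the narrative R² sequence (0.33 … 0.71), the stated RMSE
range (0.49–0.52 mg/dm²), and EW-scale plausibility of predictions on
realistic reflectance. The EWM-1 cell "0.4652" could in principle split as
0.465/2 rather than 0.46/52; only the latter yields wax-scale output on
realistic blue reflectance, so it is the adopted parse.

## Re-calibration machinery

**LOOCV.** Cross-validated R² = 1 − PRESS/SST, with PRESS computed through
the exact hat-matrix identity e₍ᵢ₎ = eᵢ/(1 − hᵢᵢ); the test suite verifies
equality with literal n single-deletion refits to 1e−10. The value may be
negative (model worse than the mean). For ranking candidate indices the
cross-validation runs in the trait-on-index direction, matching how
calibration quality is usually reported; both directions are available.

**Bootstrap RMSE.** Each of 1000 replicates draws a random 2/3 calibration
split, fits the calibration line, inverse-predicts the held-out third, and
records the RMSE against measured wax; the summary is the replicate mean
with a 2.5/97.5 percentile interval. Degenerate splits (zero wax variance)
are redrawn, up to 100 attempts. Fully reproducible from the seed.

**Per-band wax slopes.** Band-wise OLS of reflectance on wax load; the
slope is d(reflectance)/d(EW) in fraction per mg/dm², with a two-sided
t-test per band. (Slopes in this direction — reflectance response per unit
wax — are the physically meaningful quantity; a description of the same
regression with the variable roles swapped in labeling would make the
reported "slope" dimensionally wrong.)

**PLS.** NIPALS PLS1 on mean-centered data (no unit-variance scaling by
default: reflectance bands share units; scaling sits behind a flag). The
implementation exposes scores T, loadings P and the residual E with
X_centered = TP′ + E holding by construction and T′T diagonal; at full rank
its predictions coincide with OLS. `plsr_fit` splits 2/3 train : 1/3
validation, picks the component count by minimum LOOCV RMSEP on the
training split, and reports percent response-variance per component plus a
coefficient-magnitude ranking of wavelengths. sklearn's PLSRegression
(scale=False) is used in the test suite as an independent cross-check of
the NIPALS implementation, never as the implementation.

**Stepwise / Mallows' Cp.** Forward selection by the significance of the
partial F statistic (entry α = 0.15, the classical stepwise default, as the
source names only the software used, not its α), with backward elimination
at the same threshold. Every visited model is scored by
Cp = SSE_p/σ̂²_full − n + 2p (p counting the intercept; σ̂² from the full
candidate model, exactly collinear candidates dropped first with a
warning); the reported model is the Cp minimizer along the visited path,
refit by OLS, with RMSE on a 40 % hold-out. An SSE below 1e−12·SST is
treated as a perfect fit — partial F-tests on rounding residue are noise.
Greedy stepwise is not guaranteed to visit the global best-subset optimum;
the oracle-equivalence tests therefore use designs (near-orthogonal
predictors, dominant true effects) where greedy demonstrably is optimal,
and under a pure-noise response the first-entry rate is checked against the
best-of-k theory value 1 − (1 − α)^k rather than against an (impossible)
no-entry expectation.

## Quantitative genetics

Variance components come from the balanced genotype × replicate two-way
ANOVA via expected mean squares: σ̂²e = MS_error, σ̂²g = (MS_genotype −
MS_error)/r, negative moment estimates truncated to zero with a warning.
This balanced method-of-moments estimator deliberately replaces the
incomplete-block (alpha-lattice) REML used on the original field data: it
is assumption-light, exactly reproducible, and reproduces the published
heritability cells that are internally consistent at r = 2. Heritability is
entry-mean based, h² = σ²g/(σ²g + σ²e/r). (Several published cells are
*not* consistent with their own printed variance components at r = 2 —
presumably block-variance terms or unrounded inputs upstream; those cells
are not targets of the worked examples.)

Genotypic covariance is the plug-in covariance of genotype means — the
simplest estimator consistent with r_g = COV_XY/√(Var_x·Var_y); moment
estimates of r_g can exceed |1| and are flagged, not clipped. The selection
differential SDiff (= K) is |mean(selected fraction) − population mean| at
the given selection pressure (default 10 %) with an explicit high/low
direction flag — the magnitude convention keeps GG = h²·SDiff positive
under upward selection regardless of how the subtraction is written.
GA = K·σ_p·h², GAM = 100·GA/mean, R = h·σ_g, CR = h_x·r_g·σ_gy (signed:
negative genotypic correlation gives negative correlated response), and
RE = CR/R computed from unrounded intermediates.

## Aerial empirical line

Per spectral band, OLS of the tarps' *measured* reflectance (ground
spectroradiometer truth — not their nominal 8/16/32/48 % levels, which are
metadata/QC only) on their digital counts; applying the lines to plot-level
DC tables yields canopy reflectance. With two tarps the line interpolates
exactly; a band with no DC spread raises, naming the band. Calibrated
values outside [0, 1.2] are flagged, not clipped. Image georeferencing and
per-plot DC extraction are upstream of this package; it consumes extracted
DC tables.

## The synthetic generator

`baseline_leaf_spectrum` is a parametric green-leaf shape: a visible-range
pigment profile (0.05 floor with a Gaussian green bump at 550 nm) blended
into a 0.45 NIR plateau through a logistic red edge centered at 715 nm
(scale 9 nm). It is smooth, strictly positive, below 0.6, and monotone
through 700–740 nm.

The wax-effect profile encodes the empirically measured linear reflectance
response per mg/dm² of wax: +0.0082 over 424–450 nm, +0.0079 over
544–575 nm, −0.0077 over 713–720 nm deepening to −0.008 at the 717 nm
peak, and +0.015 over 756–825 nm, with 3-nm (one grid cell) cosine tapers
at segment edges to avoid non-physical steps, and exactly zero elsewhere —
including 575–713 nm and above 825 nm, where no response has been
quantified (set to zero rather than interpolated). Consequences worth
knowing: EWI-13/EWI-14 read bands (625, 736, 832 nm) that all fall in
these zero-gaps, so under the default profile those two indices are
wax-insensitive even though they are among the strongest indices on real
leaves; synthetic association tests therefore assert on indices whose
bands lie inside the responsive windows.

`simulate_trial` draws genotype effects ~ N(0, σ²g) around the population
mean and plot errors ~ N(0, σ²e) — defaults g = 50, r = 2, mean
1.72 mg/dm², σ²g = σ²e = 0.014, the scale of a replicated wheat trial —
and renders each plot spectrum as the baseline (optionally scaled by a
ground-cover factor in (0.5, 1]) plus EW·profile plus band noise.
`spectral_noise_sd` (default 0.005) is *per reading*; each plot spectrum is
the average of `n_readings` = 10 readings, matching the standard field
protocol, so the effective band noise is 0.005/√10 ≈ 0.0016.
`simulate_leaf_panel` instead spans a wide wax range (uniform
0.5–4 mg/dm²), emulating a single-leaf calibration set: within-trial trait
variation (SD ≈ 0.17 mg/dm²) is too small for strong single-band
index–trait correlations at realistic noise — as the modest field
phenotypic correlations of real trials also show — whereas the calibration
panel supports |r| well above 0.5 for responsive indices. All generators
are pure functions of (config, seed).

What passing tests on this generator do **not** show: canopy architecture,
soil background, trichome and leaf-geometry effects, instrument
nonlinearity, and wax responses outside the four measured windows are all
absent, so synthetic performance bounds nothing about field accuracy; the
generator's role is to verify the estimators recover what was injected.

## Numerical choices and degenerate inputs

Tolerances: NIPALS stops early if the response deflates to zero;
reconstruction and orthogonality hold to 1e−10 in tests; full-rank
PLS = OLS to 1e−8. LOOCV equals its brute-force oracle to 1e−10.
Reflectance above 1 is rejected unless a calibration-noise flag is set
(empirical-line output can overshoot 100 %). White ≤ dark at any band,
empty clip ranges, grid mismatches among replicates, constant wax in slope
fits, zero total sum of squares in LOOCV, unbalanced trials, single
genotypes, zero calibration slopes and zero-spread tarp bands all raise
typed, named errors rather than propagating NaNs.

## Problem sizes

Default test and acceptance runs use: 200-band 3-nm grids (400–997 nm),
100-plot trials (g = 50, r = 2), 100-leaf panels, 500-trial Monte-Carlo
recovery of σ²g, 200-seed heritability sampling distributions, 1000 (tests:
200–500) bootstrap replicates, and exhaustive best-subset enumeration up to
8 candidate bands. The full suite runs in well under a minute on one CPU.

## Known limitations

- Incomplete-block (alpha-lattice) REML variance components are out of
  scope; unbalanced trials are rejected rather than approximated.
- No radiative-transfer canopy model (PROSPECT/SAIL); canopy is a scalar
  ground-cover multiplier on the leaf spectrum.
- No smoothing/derivative spectroscopy; indices are computed on the
  resampled grid as-is.
- Built-in calibration constants transfer only to spectra comparable to
  the field material they were fitted on.
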