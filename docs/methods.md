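# Methods

## Problem and scope

The package calibrates a mid-infrared (ATR) spectrometer to report ethanol
concentration in fermented beverages directly from the 1200–850 cm⁻¹
fingerprint region.  Ethanol absorbs there through C–O stretching
(1200–950 cm⁻¹) and O–H bending (900–850 cm⁻¹); fermentation sugars
(glucose, fructose, sucrose, maltose) absorb in the same window, so the
calibration must be multivariate.  Six concerns are separated into modules:
spectral I/O (`spectra_io`), pre-treatment (`preprocess`), the PLS1 model
with its selection and comparison machinery (`pls_model`), validation
statistics (`metrics`), the GC-FID reference calibration (`gc_calibration`),
and a synthetic-data generator (`synth_spectra`).

## Spectral data model

Spectra live on a uniform, strictly increasing wavenumber grid; instrument
exports in descending order are flipped on ingestion (together with their
absorbance columns) so derivative signs are unambiguous.  Uniformity is
enforced to 10⁻⁶ relative tolerance because the Savitzky–Golay filters
assume equidistant abscissae.  The standard working region, 850–1200 cm⁻¹
at 1 cm⁻¹, has exactly 351 variables.  Replicate spectra (triplicate
measurement is the norm) are combined by the pointwise arithmetic mean.
Readers accept simple CSV (header row, `wavenumber_cm-1` column) and
single-spectrum JCAMP-DX (AFFN `(X++(Y..Y))` XYDATA and XYPOINTS;
transmittance is converted to absorbance as −log₁₀T).  Compressed JCAMP
encodings (SQZ/DIF) and atmospheric/ATR corrections are out of scope —
spectra are expected already backgrounded in absorbance units.

## Pre-treatment

Four operators, composable in any order:

| operator | action | state |
|---|---|---|
| subtract_minimum | per-spectrum minimum → 0 | none |
| normalize | per-spectrum min–max to [0, 1] (alternatives: unit-vector, unit-area) | none |
| derivative | Savitzky–Golay smoothed 1st/2nd derivative per cm⁻¹ | none |
| mean_center | subtract per-wavenumber column means | means learned on calibration |

Twelve named chains ("raw" plus eleven combinations beginning with minimum
subtraction) form the comparison set.  The derivative algorithm is a design
choice — the operator is only specified as "1st/2nd derivative" in
chemometric practice — and Savitzky–Golay with window 9 and polynomial
order 2 (1st) / 3 (2nd) is the standard noise-aware choice; plain finite
differences would amplify exactly the noise the window suppresses.  Output
length equals input length (scipy's `mode="interp"`: the end points are
evaluated from the polynomial fitted to the first/last full window), so the
351-variable count survives every chain.  "Normalization" is likewise
underdetermined in common usage; min–max is the default here, logged in the
model metadata, with unit-vector and unit-area as explicit alternatives.
Derivatives are computed after restricting to the working region; edge
effects therefore sit at 850 and 1200 cm⁻¹, away from the strongest ethanol
bands.  A pipeline fitted on the calibration block stores its stateful
parameters (column means) and applies them unchanged to prediction samples;
re-estimating them on new data would both leak information in
cross-validation and make predictions depend on the prediction batch.

## PLS1 and model selection

NIPALS PLS1 with X-side deflation only (y-side deflation is algebraically
redundant for one response).  The implementation is deterministic — each
latent variable is a closed-form covariance direction — and satisfies two
strong internal checks used in the test suite: score vectors are mutually
orthogonal, and with as many latent variables as the rank of the centred
X-block the fitted values coincide with (minimum-norm) least squares.
scikit-learn's `PLSRegression` is used in the tests as an independent
oracle, never in the implementation.

Cross-validation is leave-one-out: one standard held out per fold, the
pre-treatment state and the PLS model both re-fitted on the remaining
standards, and the held-out spectrum predicted — n standards give n
sub-models and n out-of-fold predictions.  The latent-variable count is the
smallest A whose RMSECV lies within 2 % (relative, configurable) of the
curve minimum; if the data run out of rank before `max_lv` the curve is
truncated there.  The pre-treatment comparison table ranks chains
lexicographically by higher R²pred, lower RMSEP, fewer latent variables,
then input order; a chain that fails on the data (e.g. normalization of a
flat spectrum) is recorded as a failed row rather than aborting the table.
PCA screening (centred SVD) flags samples whose Hotelling T² over the
retained components exceeds the (1−α) F-limit, α = 0.05 by default; it
warns and never drops.

## Validation statistics

RMSE-family errors are √(Σe²/n); SEC/SECV/SEP use √(Σe²/(n−A−1)), the
degrees-of-freedom correction for a model with A latent variables plus an
intercept (so RMSE ≤ SE always, and the two converge as n grows).  Spike
recovery is 100·(spiked − unspiked)/added, kept at full precision
internally and rounded to 3 significant figures only for presentation.
Method agreement is a two-sided paired t-test at α = 0.05; identical paired
vectors return p = 1 by convention rather than the undefined 0/0 statistic.

## GC-FID reference calibration

The reference method regresses the ethanol:n-propanol peak-area ratio on
concentration by ordinary least squares (≥ 3 standards, residual σ with
n − 2 degrees of freedom).  Detection limits follow the 3σ/10σ residual
rule, LOD = 3σ/|slope| and LOQ = 10σ/|slope| (LOQ/LOD = 10/3 exactly); the
residual standard deviation of the regression is used as σ, the standard
reading of the "σ of the intercept/residuals" family of prescriptions.
The bundled % w/w → % v/v conversion is the empirical affine map
1.21879·x + 0.13712.  Its intercept is non-physical (0.137 % v/v at zero
ethanol) but is reproduced as published because predictions quoted in % v/v
must be comparable with reference values produced the same way; a
density-based conversion (zero maps to zero) is provided as a clearly
separate, non-default alternative.

## Synthetic-data generator

The generator emulates the calibration campaign itself: 25 standards with
ethanol uniform on [2, 10] % w/w and each sugar uniform on [0, 5] % w/w,
drawn independently (a design stated only as "uncorrelated"; a Latin
hypercube would also qualify but plain independent draws are the simpler
faithful default).  Mixture spectra are Beer–Lambert additive — the
concentration-weighted sum of Gaussian-band pure-component spectra — plus
optional per-measurement quadratic baseline drift and i.i.d. Gaussian noise
(default σ = 5×10⁻⁴ AU, a realistic absorbance-noise scale for a 32-scan
ATR measurement), in triplicate.  All randomness flows from one seed.

Band centres follow the usual assignments (ethanol 1087/1045/880 cm⁻¹;
sugar fingerprints clustered at 980–1080 cm⁻¹, overlapping ethanol);
widths (σ 6–11 cm⁻¹, FWHM ≈ 14–26 cm⁻¹, typical of liquid-phase
fingerprint bands) and amplitudes (~0.1 AU peak at 10 % w/w, ATR scale)
are synthetic fixtures shipped in `data/default_bands.yaml`.  The widths
matter: the generator's contract is that ethanol be recoverable at
RMSECV ≤ 0.1 % w/w under the 2nd-derivative pipeline at default noise, and
since second-derivative signal scales as amplitude/width², substantially
broader bands would carry too little curvature to clear instrument noise.
Under the defaults the measured RMSECV is ≈ 0.05 % w/w with
R²(cal/CV) ≥ 0.999, with the error rising monotonically as noise is
increased and derivative chains overtaking normalization chains once
baseline drift is injected — the qualitative behaviour a practitioner
expects from real instruments.

What the simulator does not model: real beverage matrices (proteins,
polyphenols, organic acids), ATR effective-pathlength dispersion,
temperature effects, water-band subtraction artefacts, and CO₂/water-vapour
lines.  Passing tests on simulated data therefore demonstrate the
correctness and noise behaviour of the algorithms, not the accuracy of any
particular instrument's calibration; a real deployment still needs its own
validation set and spike recoveries.  Note also that additive Gaussian
noise makes near-zero signal regions dip below zero absorbance; only the
noise-free signal plus a non-negative baseline is guaranteed non-negative.

## Numerical choices and degenerate inputs

Rank exhaustion in NIPALS (weight or score norms at machine-precision
scale) raises a rank error naming the latent variable; zero-variance y,
flat spectra under min–max normalization, < 3 GC points, and non-positive
spike additions are all rejected with specific errors rather than silently
producing NaNs.  Negative quantified concentrations are flagged, not
clipped.  Ties in the comparison ranking are broken toward fewer latent
variables, then input order.  Problem sizes throughout the test suite and
the acceptance script mirror the study design itself (25 standards,
351 variables, triplicates), which runs in seconds.
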