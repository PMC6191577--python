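# Methods

## The analysis chain

The package evaluates three routes from proximal optical measurements to
the biomass and nitrogen status of young wheat stands: (1) the green-pixel
fraction of nadir RGB photographs, (2) two-band normalized-difference
spectral indices — a fixed 12-index battery plus an exhaustive per-trait
optimization over all wavelength pairs — and (3) full-spectrum PLSR.  All
three are scored against four destructively measured traits: fresh weight,
dry weight, N concentration and N uptake (= dry weight × N % / 100, an
exact identity maintained everywhere).

### Green-pixel segmentation

Images are converted to HSB with all three channels on the 0–255 byte
scale.  This is the ImageJ color-threshold convention, and the default
green band hue ∈ [45, 120] is defined on it (≈ 63.5°–169.4°).  Many
libraries express hue in degrees or [0, 1] floats; thresholds from those
conventions must be rescaled before use here.  Intervals are closed at
both ends, matching integer byte semantics.  Achromatic pixels (max = min)
are assigned hue 0 and saturation 0, so gray/black/white can never be
classified as plant.  The hexcone transform is implemented to be
bit-identical to the textbook per-pixel formulation (the stdlib `colorsys`
serves as the oracle in the tests); distinct colors are converted once per
image and scattered back, since photographs contain far fewer colors than
pixels.  No hue wraparound is supported (lo ≤ hi); the green band does not
wrap.  An optional rectangular crop stands in for the physical reference
frame cut out of field photographs; there is no shadow correction or white
balancing, which are controlled at acquisition.

### Spectral indices and contour maps

Spectra live on a data-defined, strictly increasing nm grid (the reference
instrument samples 302–1148 nm at 2 nm).  Band lookup snaps to the nearest
band center, ties to the lower wavelength, and refuses requests farther
than half a grid step from any center.  All indices are of the normalized
difference form; a zero denominator yields NaN, never a silent zero.  One
battery entry is worth a note: the 624/572 index is implemented in the
symmetric form (R₆₂₄ − R₅₇₂)/(R₆₂₄ + R₅₇₂); an asymmetric denominator
(R₆₂₄ + R₆₇₂) circulates in print but is inconsistent with the index's own
name and with every other battery member.

A contour map for trait y holds R² of the simple linear regression of y on
NDSI(λi, λj) for every unordered pair in a configurable range (default
302–1048 nm).  For simple regression R² equals the squared Pearson
correlation, which the implementation exploits: the inner loop computes
the strict upper triangle vectorized over the second band and mirrors it,
making the map symmetric to the bit and a full 424-band map (89,676 pairs,
64 plots) a sub-second operation.  Per-date maps are aggregated by
entrywise arithmetic mean (no weighting by per-date n); masked cells
(undefined NDSI for any plot, degenerate regression, the diagonal)
propagate through the mean.  The best pair is the global off-diagonal
maximum, ties broken to the lexicographically smallest pair.

### Regression

`fit_linear` is ordinary least squares with the two-sided slope t-test
(n − 2 df); `fit_quadratic` adds an x² term and uses the overall F test.
Significance stars follow the nominal α levels 0.05 / 0.01 / 0.001 with
no multiplicity adjustment (tables report per-test stars).  The pipeline
default is linear everywhere; the quadratic form is an explicit opt-in for
green-fraction relationships, which become curvilinear once cover passes
roughly 45 %, and both are then reported side by side.

### PLSR

Traits are regressed on all bands in 400–1000 nm.  Preprocessing is
mean-centering only; band autoscaling is a documented switch, off by
default.  Cross-validation uses seeded, size-balanced random k-folds
(default k = 7) — plots carry no meaningful order here, so contiguous
blocks would only encode an artifact of row order.  For each candidate
component count 1…10 the out-of-fold predictions are pooled; the count
minimizing pooled RMSEV wins (ties to the fewer components, the standard
parsimony convention), and the final model is refit on all data at that
count.  Definitions: R²cal = 1 − SSE/SST on training data,
RMSEC = √(SSE/n); R²val = 1 − PRESS/SST on pooled out-of-fold predictions,
RMSEV = √(PRESS/n); slopes are from regressing predictions on
observations.  Two structural facts the tests pin down: slope_cal equals
R²cal exactly (a least-squares identity), and a 2-component model
interpolates a noiseless linear response only when the predictor matrix
itself has two degrees of freedom — with many independent bands, PLS
components span a Krylov subspace that need not contain the true
coefficient vector.

## The synthetic canopy generator

No public dataset pairs early-tillering wheat spectra, images and
destructive traits, so the package ships a generator that emulates the
statistical structure the analysis assumes.  It is first-class, tested
code, and its defaults define the package's study conditions.

**Traits.**  Each sampling date carries (min, mean, max) targets per trait.
Sampling uses a truncated normal on [min, max] with spread fixed at
(max − min)/4 and location solved so the truncated mean hits the target —
min/mean/max summaries pin down exactly these two degrees of freedom.
Within a date, plots share a latent vigor factor that loads positively on
both biomass traits and negatively (loading 0.4) on N concentration,
reproducing the within-date face of N dilution; `noise_sd_trait` (default
0.5) sets the idiosyncratic share.  Point-mass targets (min = mean = max)
are legal and yield identical plots.  The default "2014-like" season (64
plots × 4 dates, BBCH 19→30) has dry weight rising from a mean of
450 to 2206 kg ha⁻¹ while N % falls from 3.2 to 2.0 — the dilution effect;
the "2016-like" season (30 plots × 2 dates) reverses the N trend,
emulating fertilization between samplings.  The 2016 season's fresh-weight
targets are derived from dry weight at a typical 20 % dry-matter fraction
(only dry weight was tabulated for that season); N-uptake ranges are
reference metadata, since uptake is always derived from the identity.

**Canopy closure.**  Fractional cover follows a Beer–Lambert form
f = 1 − exp(−k·W) with W the dry weight and k = 5 × 10⁻⁴ ha kg⁻¹ by
default.  This is near-linear at low biomass and concave throughout, so
green cover loses sensitivity to biomass as the canopy closes — visibly so
above ~80 % cover, where the marginal gain per kg falls below a quarter of
the initial slope.  A single k cannot reproduce all four observed per-date
mean covers simultaneously (18.8→61.9 % against means 450→2206 kg ha⁻¹);
k = 5 × 10⁻⁴ spans ~20→67 %, bracketing that trajectory, and was fixed
once as the default.

**Spectra.**  Plot reflectance is a linear two-endmember mixture
R(λ) = f·R_veg(λ; chl) + (1 − f)·R_soil(λ) + ε with ε i.i.d. Gaussian band
noise (default σ = 0.004 reflectance units), clipped to [0, 1].  The soil
endmember is a bright monotone ramp (0.08→0.30); vegetation has a green
peak at 550 nm, a red absorption trough at ~670 nm whose depth grows with
a chlorophyll proxy, a logistic red edge whose inflection shifts from 702
to 720 nm with the proxy, and a NIR plateau at 0.48.  The proxy is affine
in N concentration (clip((N% − 1)/4.5, 0, 1)), which is what gives
red-edge indices an N signal distinct from pure biomass.  With zero noise
the spectrum is a deterministic function of the traits, and NDVI is
strictly increasing in dry weight at fixed N %.

**Images.**  A scene with target green fraction g plants exactly
round(g/100 × width × height) pixels with colors drawn from a palette
verified to fall inside the byte-scale green thresholds; all other pixels
come from palettes verified to fall outside (soil browns; in the
`winter_stressed` style also yellow-brown stressed-leaf hues just below
the green band, mimicking cold-damaged early canopies).  Pixels are i.i.d.
with no spatial texture — the green-fraction statistic is spatially
agnostic, so texture would be cosmetic.  The generator returns the planted
count as ground truth, enabling exact round-trip tests.

**Determinism.**  Every random stream is keyed on the scenario seed plus a
stage tag and the (plot, date) identity, so identical scenarios reproduce
traits, spectra and images bit for bit, independent of generation order.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no radiative transfer (no PROSAIL-class
leaf/canopy model), no BRDF, sun-angle, shadow or soil-moisture effects,
no spatial canopy structure (row geometry, overlapping leaves), no sensor
noise model beyond additive Gaussian, and trait–spectrum coupling is exact
up to that noise.  Skill metrics on synthetic seasons are therefore upper
bounds on field performance; the package's claims are about the
correctness and stability of the *methods*, not about field-transferable
accuracy values.

## Numerical choices and degenerate inputs

* Reflectance is validated to [0, 1.5], tolerating calibration overshoot.
* Band-lookup ties round down; out-of-span requests raise.
* Regression refuses n < 3 (linear) / n < 4 (quadratic), constant
  predictors and constant responses; the quadratic F statistic is computed
  from sums of squares directly so an exact fit does not divide by zero.
* Contour maps refuse fewer than 3 observations and constant traits; NaN
  marks masked cells rather than sentinel zeros.
* PLSR caps candidate components at min(requested, smallest training-fold
  size − 1, band count); component ties go to the fewer.
* The pipeline joins observation tables on (plot_id, date_id), reports
  orphaned keys as diagnostics, proceeds on the intersection, and fails
  only on duplicates or an empty intersection.

## Problem sizes

Default analyses run at 64 plots × 4 dates with 128 × 128 px images, a
374-band contour range and 301-band PLSR range — a desk-scale season that
keeps the full pipeline under ~10 s while preserving the structure of the
field campaign (its cameras produced 3696 × 2448 px frames; image size is
a config parameter, not a contract).
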