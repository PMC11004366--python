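# Methods

This note documents the models implemented in `grazecap`, the parameters
that matter, the synthetic-scene construction, and the design choices made
where the underlying methodology leaves room.

## 1. Cross-sensor NDVI fusion

Long NDVI records are stitched from a legacy sensor (coarse, long archive)
and a modern sensor (shorter archive). Over the overlap months the legacy
value G at each pixel is modelled as

    G = a + b·V + ε,

fitted by ordinary least squares with all overlap months pooled in one fit
per pixel (an optional per-calendar-month variant is not provided; pooling
uses every overlap sample and is the common practice for this calibration).
The harmonized series keeps modern months verbatim and maps legacy months to
the modern scale by inverting the pixel's own fit, `V̂ = (G − a)/b`, clipped
to the physical NDVI range [−0.2, 1]. Pixels with fewer than two valid
overlap pairs, a constant regressor, or |b| < 1e−8 are flagged and become
nodata in the mapped era — extrapolating through a degenerate fit would
fabricate data.

The estimators are the closed-form normal-equation solutions; the test suite
checks them against `scipy.stats.linregress` and `numpy.linalg.lstsq` to
1e−10 on random short series.

## 2. CASA light-use-efficiency NPP

    NPP(x,t) = APAR(x,t) · ε(x,t)        [gC m⁻² month⁻¹]
    APAR     = SOL · FPAR · 0.5          [MJ m⁻² month⁻¹]
    ε        = Tε1 · Tε2 · Wε · ε_max    [gC/MJ]

* **FPAR** ramps linearly in NDVI between a per-grassland-type envelope —
  the 5th/95th percentiles (configurable) of that type's full monthly NDVI
  history — and is clipped to [fpar_min, fpar_max] = [0.001, 0.95].
  Percentile envelopes are robust to outliers; they also make FPAR adaptive
  per type (each type's observed NDVI range spans the full FPAR range).
* **Tε1** = 0.8 + 0.02·Topt − 0.0005·Topt², where Topt is the pixel's mean
  temperature in its peak-NDVI month (multi-year climatology); maximal (1.0)
  at Topt = 20 °C, clipped at 0.
* **Tε2** = 1.1814 / [(1 + e^{0.2(Topt−10−T)})(1 + e^{0.3(−Topt−10+T)})],
  the standard asymmetric penalty for months colder or hotter than the
  pixel's optimum.
* **Wε** = floor + (1 − floor)·E/Ep with floor = 0.5 by default. No
  soil-moisture bucket is carried; the shipped evapotranspiration closure is
  E/Ep ≈ clip(P / PET, 0, 1) with PET from Thornthwaite's temperature
  formula (monthly heat index from the pixel's temperature climatology,
  no day-length correction — immaterial in a 0–1 ratio). Months at or below
  0 °C have PET = 0 and sit at the floor. A different closure can be passed
  as a callable.
* **ε_max** defaults to 0.542 gC/MJ, a widely used grassland value; a
  per-type table can be supplied. There is deliberately no hidden per-type
  default: the single fallback is visible in the configuration.

The product form is dimensionally forced: MJ m⁻² × gC/MJ → gC m⁻². All four
sub-factor grids can be emitted (`return_factors=True`) and are individually
bounded in [0, 1.1], which the tests assert on full scenes.

## 3. Forage yield and carrying capacity

Aboveground allocation is linear in monthly mean temperature,
`fANPP = 0.171 + 0.0129·MAT`, **clamped to [0, 1]**: the unclamped line goes
negative below −13.26 °C, which cold-winter rangelands reach routinely, and
negative biomass is unphysical. Yield is `F = NPP·fANPP / 0.47` in g/m²
(0.47 gC per g dry matter); the kg/hm² view is exactly 10× and the tests
hold that identity to machine precision.

Carrying capacity per pixel:

    CC = AGB · Gᵢ / (L · D)     [SU hm⁻²]

with AGB in kg/hm², utilization rate Gᵢ per grassland type (configuration is
mandatory — `default_utilization()` provides an explicit, visible table:
meadow 0.60, alpine/subalpine meadow 0.55, plain 0.50, alpine/subalpine
grassland 0.45, desert 0.40), intake L = 1.8 kg SU⁻¹ d⁻¹ and grazing days D.

**Accounting windows.** Months use their calendar day count and years use
365. All *seasonal* windows — spring (MAM), summer (JJA), autumn (SON),
winter (DJF within the calendar year) and the April–October growing
season — share one common D of 92 days. This is a deliberate normalization:
with a common denominator, seasonal capacities are directly comparable as
"stocking rate supported by that window's forage on a standard season", and
the growing season (whose forage pool is the union of several seasons)
correctly ranks above summer. Dividing each window by its own length would
instead make the growing-season figure a *mean daily* rate, which can never
exceed the summer rate because summer is the growing season's peak — a
comparison of means, not of forage pools. Both D values are configurable
(`CapacityParams.season_days`, `year_days`).

Season definitions themselves are configuration-level constants
(`SEASON_MONTHS`); winter pools December with January/February of the same
calendar year to keep windows within years.

## 4. Grass–livestock balance

Herds convert to standard sheep units with the customary factors (cattle,
horse, mule 5; donkey 2.5; camel 8; sheep 1.2; goat 0.8 SU per head — the
sheep factor above 1 reflects a regional "standard sheep" lighter than the
local breeds; it is configurable). County theoretical capacity CA is the
zonal sum of the annual capacity raster times pixel area over the county's
grassland pixels.

    Ip = (A − CA)/CA · 100%
    grade: I (Ip ≤ 0), II (0 < Ip ≤ 25), III (25 < Ip ≤ 50), IV (Ip > 50)

Ip = 0 — load exactly at capacity — is assigned to grade I ("not
overloaded") because capacity is not exceeded; the conventional band
definitions leave this boundary point open. CA ≤ 0 (a county without
grassland) yields an undefined index with an explicit flag rather than ±∞.

The regional yearly summary reports both a capacity-weighted mean index,
(ΣA − ΣCA)/ΣCA, and the unweighted county mean; the two differ whenever
small-capacity counties are disproportionately overloaded.

## 5. Trend and persistence diagnostics

* **Theil–Sen slope**: median of all pairwise slopes; exact brute-force
  semantics, checked against `scipy.stats.theilslopes`.
* **Mann–Kendall**: S = ΣΣ sign(xⱼ − xᵢ), variance with the standard tie
  correction, Z with the ±1 continuity correction; significance at
  α = 0.05 (|Z| ≥ 1.96) by default. The suite verifies the empirical type-I
  error on Gaussian null series of length 39 (a typical multi-decadal
  record) is 5% ± 1.5%.
* **Trend classes**: SD/NSD/NSI/SI from the Sen sign × MK significance; a
  Sen slope of exactly 0 goes to NSI — an arbitrary but deterministic
  tie-break.
* **CV stability**: sample SD over mean, classed by configurable breakpoints
  (default 0.1/0.2/0.3) into stable / relatively stable / unstable / highly
  unstable; undefined for non-positive means.
* **Hurst exponent**: classical rescaled-range analysis over dyadic window
  lengths (8, 16, …, n/2), H = slope of log mean(R/S) vs log window length;
  requires ≥ 32 points, so it is computed on the monthly rather than the
  annual stack. Small-sample R/S is biased upward on white noise; the
  calibration test asserts the mean estimate over 50 replicates of length
  512 falls in [0.45, 0.65], and a deterministic ramp saturates above 0.9.
  H > 0.5 with the current Sen sign is read as trend continuation, H < 0.5
  as likely reversal.

## 6. Geographical detector

Factor power of a stratification for a response:

    q = 1 − Σ_h N_h σ_h² / (N σ²)    (population variances)

Population variances make q exactly 1 − SSW/SST, so q ∈ [0, 1], q is
invariant under affine transforms of the response, and the overlay
(cross-classification) of two stratifications can only refine the partition,
hence `q_ab ≥ max(q_a, q_b)` holds exactly — the tests assert it without
tolerance. Interaction categories follow the standard comparison rules
(nonlinear-weaken / univariate-weaken / bivariate-enhance / independent /
nonlinear-enhance); the tie `q_ab = max(q_a, q_b)` is labelled
univariate-weaken with a boundary flag. Continuous drivers are discretized
by quantiles (k = 5 default; equal-interval and 1-D-k-means natural breaks
available); integer rasters pass through as given strata. Significance is
available via a seeded permutation test rather than the noncentral-F
approximation — simpler and assumption-free. Pixels are subsampled (seeded)
to at most 50,000 samples.

## 7. The synthetic scene

The generator emulates the statistical structure the pipeline assumes, with
every "unknown" recorded as ground truth:

* **Drivers** (elevation, slope, aspect, SOM, population density, GDP,
  drought index, plus annual-mean temperature and precipitation) are
  smoothed Gaussian random fields, **QR-decorrelated**: on a desk-scale grid
  a smooth field has few independent blobs, and chance correlations between
  raw fields would blur which driver truly explains productivity.
* **Productivity** is a weighted sum of rank-uniformized driver transforms —
  monotone for most drivers, unimodal in elevation (a mid-elevation optimum)
  — plus unstructured noise. Rank uniformization gives every transform the
  same marginal variance so the configured weights map directly onto
  explanatory-power ordering. Default weights: precipitation 1.0, elevation
  0.90, SOM 0.60, temperature 0.36, drought index 0.12, population density
  0.06, GDP 0.05, slope 0.03, aspect 0.01.
* **NDVI** follows a skewed annual bell peaking in July (σ = 2.8 months
  before the peak, 2.0 after, so spring NDVI exceeds autumn NDVI), with
  amplitude 0.08 + 0.36·productivity, a spatially varying linear trend
  (about 80% of pixels greening, the rest browning) and 5% interannual
  amplitude jitter. Values are clipped to [−0.2, 1].
* **Sensors**: the modern record is the latent NDVI over the tail years; the
  legacy record is `a + b·latent + N(0, noise_sd)` over the whole span
  (defaults a = 0.05, b = 0.9, noise 0.01). With noise 0 the fusion stage
  must recover the latent record to machine precision, and the tests hold it
  to 1e−9.
* **Climate**: temperature = spatial base (8–10 °C) + 14 °C annual cosine
  peaking in July; precipitation distributes an annual total (150–350 mm)
  over a summer-peaked monthly profile; solar radiation is an annual cosine
  (≈ 2160 MJ m⁻² yr⁻¹). The radiation level is set low deliberately: the
  percentile-based FPAR envelope is adaptive and yields higher FPAR than
  fixed-envelope formulations, and the product was scaled so scene NPP lands
  in the observed arid-steppe range (≈ 180 gC m⁻² yr⁻¹).
* **Types and counties**: five grassland classes as quantile strata of the
  moisture gradient (4% of pixels non-grassland), counties as a rectangular
  tiling — exact zonal bookkeeping with no polygon machinery. A contiguous
  ~3% nodata blob is shared across all layers.
* **Herds**: seven species with a fixed composition; each county-year's
  total sheep-unit load is set against the scene's *own* pipeline-computed
  theoretical capacity to hit a requested overload grade (representative
  indices −20 / 12.5 / 37.5 / 75% for grades I–IV — band midpoints, so
  integer rounding of head counts cannot cross a 0/25/50 boundary). On
  noiseless scenes the balance stage therefore recovers requested grades
  exactly, which the tests assert.

**What the scene does not emulate** — and hence what passing tests do not
show about real data: sensor-specific radiometry and atmospheric artefacts,
phenological asymmetries beyond the fixed seasonal bell, spatially
correlated driver fields (real precipitation and elevation are strongly
coupled; the scene decorrelates them on purpose to make attribution ground
truth unambiguous), reporting error in livestock statistics, and any
resampling between native sensor grids (all layers share one grid by
construction).

**Stochastic-recovery margins.** The designed driver ordering
(precipitation > elevation > SOM > temperature, aspect at the noise floor)
is a statistical property of a finite random scene. With the default
80×80 grid it is recovered for the large majority of seeds (13/15 in a
validation battery); the suite runs the package-default seed 0. Smaller
grids leave the mid-ranked drivers within sampling noise of each other.

## 8. Numerical and interface choices

* Rasters are xarray DataArrays on one shared grid, dims (time, y, x),
  month-start time axis; NaN is nodata in float layers, −1 in integer label
  layers. On disk: plain multi-page float32/int32 TIFF plus a JSON sidecar
  carrying the time axis — no geo-referencing is attached, since the
  pipeline neither reprojects nor resamples.
* Determinism: every stochastic component draws from
  `numpy.random.default_rng(seed)`; identical configuration and seed give
  byte-identical scenes and manifests.
* Problem sizes in the shipped tests (80×80×240 default scene, 32×32×120
  noiseless scene, 2,000-replicate null calibrations) were chosen as the
  smallest sizes at which the statistical checks have comfortable margins.
* Known limitations: no rodent/insect forage losses, slope or
  water-distance accessibility corrections in the capacity model; no
  pre-whitening in the Mann–Kendall test (serial correlation inflates its
  type-I error on autocorrelated series); the Hurst estimator is the
  classical R/S variant, biased upward in short samples; Thornthwaite PET
  underestimates arid-region atmospheric demand, which the 0–1 ratio
  clipping partially absorbs.
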