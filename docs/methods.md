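# Methods

`agbpipe` estimates grassland aboveground biomass (AGB) from gridded NDVI
and meteorology, maps its trends and stability, and attributes its variation
to climatic and grazing drivers. Because the archives such an analysis
normally consumes (AVHRR-era NDVI composites, station meteorology,
reanalysis soil moisture, a land-cover product) cannot ship with a package,
every stage is exercised on synthetic scenarios whose ground truth the
generator records, so each stage's skill is *measured* against known
answers rather than asserted.

## Input model and preprocessing

All gridded inputs travel as a `GridStack`: a `(time, rows, cols)` cube with
an explicit missing-value mask, units, and a pixel-centre-registered 0.05°
lattice. NetCDF I/O uses xarray's scipy (NetCDF-3) backend; categorical
rasters are TIFF with a CSV legend/affine sidecar.

The NDVI record is cleaned per pixel in a fixed order:

1. linear gap-fill (interior gaps interpolated, record ends extended with
   the nearest observation — extension avoids end-of-record extrapolation
   blow-ups);
2. interquartile-range outlier screen over the pixel's full record, fences
   `[Q1 − k·IQR, Q3 + k·IQR]` with `k = 1.5` and linear-interpolation
   (type-7) quantiles — the most common default, stated so the fences are
   reproducible;
3. re-fill of the removed cells — outliers must not anchor interpolation;
4. Savitzky-Golay smoothing, window 5, polynomial order 2 (both exposed in
   configuration), edges handled by polynomial fit over the first/last full
   window;
5. maximum-value compositing to monthly cadence.

Screening before smoothing and compositing last reflects how monthly
vegetation-index products are built; the chain re-applied to already-clean
data fills nothing, flags nothing, and only re-smooths.

Vapour pressure deficit is computed from the Tetens saturation curve,
`VPD = 0.6108·exp(17.27T/(T+237.3))·(1 − RH/100)` kPa — the standard
psychrometric definition, kept in one function so an alternative formulation
can be swapped in. The two reanalysis-style soil-moisture layers (0–7 cm,
7–28 cm) combine with thickness weights 7/28 and 21/28. Station tables, if
used instead of gridded meteorology, are gridded by inverse-distance
weighting (power 2, 8 nearest stations) — a deliberately simple, 
dependency-free choice adequate at the scales the package targets; 
thin-plate-spline surfaces are out of scope.

## NPP: light-use-efficiency model

Monthly net primary production per pixel is

    NPP = APAR · ε,   APAR = SOL · FPAR · 0.5,   ε = Tε1 · Tε2 · Wε · ε_max

with the standard grassland sub-models:

* **FPAR** ramps linearly in NDVI between per-type bounds
  (`ndvi_min = 0.023`, `ndvi_max = 0.634` by default) mapped to
  `[0.001, 0.95]` and clipped — 0.95 is the conventional canopy ceiling.
* **Tε1** `= 0.8 + 0.02·T_opt − 0.0005·T_opt²` (floored at 0, and zero in
  months with mean temperature ≤ −10 °C); **Tε2** is the double-logistic
  penalty for departure from `T_opt`, mildly asymmetric so its peak sits
  slightly above the optimum. `T_opt` defaults to the climatological mean
  temperature of each pixel's peak-NDVI month; a fixed value can be set.
* **Wε** `= 0.5 + 0.5·E/Ep ∈ [0.5, 1]` with `E = min(PPT, PET)` and PET from
  Hamon's temperature/day-length formula (needs only inputs the pipeline
  already has); a soil-moisture-ratio mode is available.
* **ε_max** defaults to 0.542 g C/MJ for grassland, per type in a packaged
  CSV.

These constants are conventional values from the light-use-efficiency
literature, shipped as editable per-type parameters rather than hard-coded:
they are assumptions of this implementation, and any of them can be replaced
from a user CSV.

Seasonal aggregation uses MAM/JJA/SON/DJF with December assigned to the
following year's winter; the record's first and last winters are therefore
incomplete and are skipped (or raise, by choice).

## Allocation, carbon and grazing intensity

The allocation rule from production carbon to standing aboveground dry
matter admits two readings; both are implemented behind a `strategy` switch:

* `carbon_partition` (default): production carbon splits between shoots and
  roots in the root:shoot biomass ratio R/S with layer carbon fractions,
  `NPP = Ca·AGB + Cb·(R/S)·AGB`, so `AGB = NPP/(Ca + (R/S)·Cb)`. This is
  the only reading that conserves carbon exactly, which the tests check per
  pixel.
* `literal`: `AGB = ANPP/[(R/S)·(Ca + Cb)]` with `ANPP = NPP/(1 + R/S)`.

Per-type parameters (R/S from 1.6 for tropical tussock to 6.8 for alpine
meadow; Ca = 0.43, Cb = 0.37 throughout) ship as a packaged CSV covering
all nine grassland classes; the two classes without published values are
mapped to the closest listed type and flagged in the table. AGB carbon
density is 0.45·AGB.

Grazing intensity is `GI = (ANPP_t − AGB_t)/(P·T)` in livestock units per
m² (×10⁴ per ha), with default intake `P = 1800` g dry matter/day per
standard sheep unit over `T = 365` days — a common husbandry convention,
both configurable. The pipeline takes `ANPP_t` as the year's aboveground
production and `AGB_t` as peak standing biomass, proxied by production
through August (the seasonal peak); later production is what grazing
removes. Negative differences have no livestock meaning and are floored at
zero with a flag raster.

## Trend, stability and attribution statistics

Per pixel over annual series: Theil-Sen slope (median of all pairwise
slopes) and the Mann-Kendall test with tie-corrected variance and the ±1
continuity correction (consequence: |S| = 1 maps to Z = 0). The normal
approximation is used at all admitted lengths (n ≥ 4); the tests compare it
against exhaustive permutation nulls at small n. Five trend classes combine
the slope against a ±0.5 g/m²/yr stable band with significance at α = 0.05;
the thresholds are explicit assumptions, exposed in configuration. The
coefficient of variation uses the sample (n−1) standard deviation; its five
fluctuation levels default to the 20/40/60/80th percentiles of valid pixels.

Driver attribution: per-pixel Pearson correlation with a two-sided t-test,
categorised SN/NSN/NSP/SP by sign and p < 0.05 (r = 0, which the strict
inequalities leave unassigned, goes to NSP); per-type correlations take the
spatial mean over the type's pixels first, then correlate in time
(pooled pixel-years are available as an option). Random-forest importance
regresses AGB on the seven drivers (T, PPT, VPD, SR, RH, SM, GI) with 1000
trees and reports seeded permutation importance, negatives floored, 
normalised to percent. Permutation importance is computed on the fitted
table via scikit-learn's public API rather than per-tree out-of-bag
scoring; on the planted-signal scenarios both give the same ordering, and
the public API keeps the result stable across library versions. The default
sampling unit is one row per pixel (temporal means), matching a single
importance number per driver; `pixel-year` rows are a switch away.

## The synthetic-data generator

`synthio` emulates the statistical structure the analysis assumes, not
sensor physics:

* **NDVI**: baseline 0.10 + amplitude 0.50 · sin²(π(m−1)/12) (July peak),
  a ±15% smooth spatial fertility pattern, Gaussian noise (sd 0.02),
  biweekly composites; a configured fraction of cells masked (5%) and of
  upward ×2 spikes (2%), positions recorded exactly.
* **Meteorology**: seasonal cycles with independent smooth spatial fields
  per variable, configurable linear trends in units/yr, Gaussian noise.
  The spatial fields' correlation length is one pixel: patches remain
  coherent while a grid still contains enough independent patches that
  per-pixel analyses are not dominated by chance field-to-field
  correlations.
* **Grazing**: lognormal around 1 LSU/ha — skewed and strictly positive, as
  stocking rates are; a censored (clipped) field would flatten planted
  signals at the low end.
* **Type map**: largest-remainder pixel counts grown as contiguous patches
  from seeded nuclei.
* **Truth AGB**: `base·f(p)·exp(Σ e_d·z_d) + s·(y − ȳ) + N(0, σ)`, floored
  at 0 — log-linear in standardised drivers so sign and ordering recovery
  are checkable by regression, plus an exact injected linear trend.
* **Truth NPP**: the forward light-use-efficiency model run on the clean
  (pre-degradation) inputs, with an admissible recovery RMSE propagated
  from the NDVI noise through the FPAR ramp
  (`3·σ_NDVI·SOL·0.5·dFPAR/dNDVI·ε̄`).

Spike placement is restricted to cells where doubling clears that pixel's
own full-record IQR fence with a 3σ margin: a doubled winter NDVI is
statistically indistinguishable from the seasonal minimum, and on lush
pixels the clip at 1.0 can keep any spike inside the fence, so unrestricted
placement would plant targets no screen could find. Downward (×0.2) spikes
are expressible in the API but not injected by default for the same reason:
the lower fence of a seasonal series sits below zero. Consequently the
measured ~100% recall shows the screen finds everything that is findable at
`k = 1.5`; it says nothing about ambiguous outliers, which real records do
contain.

What passing these tests does *not* show about real data: no orbital drift,
calibration steps, cloud-contamination structure (gaps here are missing
completely at random), spatially correlated noise, or non-stationary
seasonality. The generator is a test harness for the statistics, not a
sensor simulator.

## Problem sizes and numerical choices

Default scenarios are 12×12 pixels × 10 years (module tests), 20×20 × 35
years for trend recovery, 45×45 for the false-positive rate (≈2000 pixels),
and 28×28 × 15 years for the importance benchmark — sizes chosen so the
whole suite runs in a few minutes on one core while keeping each check
well-powered. Quantiles are type-7 throughout; means/SDs of degenerate
series raise rather than return NaN; all randomness flows from a single
`numpy` `default_rng` seed, and identical configurations are byte-identical
on disk (nothing time- or host-dependent is written).

## Known limitations

* The light-use-efficiency constants are conventional defaults, not a
  reconstruction of any particular published calibration; with real data
  they must be re-fitted or cited deliberately.
* The grazing-intensity peak-biomass proxy (production through August) is a
  convention; with observed biomass curves the peak should be taken from
  data.
* Mann-Kendall is applied without pre-whitening; strongly autocorrelated
  series would need a modified variant.
* Station gridding by IDW is not a substitute for spline surfaces over
  complex terrain.
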