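# Methods

This note documents the models, conventions, defaults and known limitations
of `snowsel`. Nothing here states an empirical result beyond what the test
suite and `scripts/acceptance.py` compute.

## Rasters and coordinate conventions

All layers live on `Grid`: a rectangular array in projected planar meters,
origin at the top-left corner, cell (row, col) centered at
`(origin_x + (col+0.5)·cell, origin_y − (row+0.5)·cell)`. Cells are
half-open: a point exactly on a shared vertical edge belongs to the cell on
the right, on a horizontal edge to the cell below. NaN is the in-memory
nodata value; it propagates through cellwise operations and is dropped from
the denominators of windowed and aggregating operations. Grids are
serialized as headered ESRI ASCII text (the package does not reproject;
inputs must be pre-aligned).

## Snow classification and indices

* **Snow-free rule.** A fine (1 m) cell is snow-free when its depth is at
  most 35 cm — the threshold is inclusive, and negative depths are rejected
  as invalid input.
* **NDSI** = (green − SWIR)/(green + SWIR); 0/0 cells become nodata. Where
  several acquisition scenes exist, their cellwise nodata-skipping mean is
  the predictor, since averaging suppresses per-scene noise.
* **TPI** is cell elevation minus the mean of a square window (default
  30 m); the center cell is excluded from the neighborhood mean (a flag
  allows inclusion), edge cells use the truncated window — no elevations are
  invented by padding. The field is demeaned before filtering so the large
  absolute elevation offset cannot cause catastrophic cancellation. The
  edge policy and center handling are conventions, both configurable,
  because no single standard exists.
* **Snow-free fraction.** Fine binary cells aggregate to the coarse (30 m)
  grid as the fraction of *valid* fine cells equal to 1. The package stores
  the snow-FREE fraction; the snow-covered complement is `1 − x`. This
  orientation lets the 80/50/30 % patch thresholds read directly.

## Snow-fraction calibration

Reference coverage is restricted to transect bands (emulating an airborne
laser-scanning subsample); each reference coarse cell must be fully covered
by fine cells. To avoid a calibration set dominated by snow-covered cells,
rows are drawn with a per-bin quota over ten 10 %-wide response bins.
Learners honor a plain fit/predict contract; built-ins are a penalized
B-spline regressor (SplineTransformer + ridge) and gradient-boosted stumps,
both able to express the curvilinear and threshold-like predictor-response
shapes, plus a linear model and a constant-mean baseline used mainly in
tests. Scoring is 5-fold cross-validation repeated 5 times (25 resamples,
folds stratified on response deciles, seeded), with out-of-fold
R² = 1 − SSE/SST; a held-out fold with zero response variance yields an
undefined (NaN) R², flagged rather than silently dropped. The final
predictor is the unweighted mean of the two best learners by mean CV R²
(ties broken toward fewer hyperparameters), refit on all rows and clipped
to [0, 1].

## Patches

A coarse cell is snow-free under a threshold scenario when its fraction is
≥ t (inclusive, "50 % or more"). Connected components default to
8-connectivity — wind-scoured ridge crests commonly run diagonally across a
grid — with 4-connectivity available. Between-patch distance is the minimum
edge-to-edge gap between cell boundaries (centroid distances are also
derivable from the table); for axis-aligned square cells this is
`hypot(max(|dx|−cell,0), max(|dy|−cell,0))` minimized over cell pairs, so
diagonally touching cells of distinct (4-connected) patches are 0 m apart.
Exclusion polygons remove any patch cell whose square intersects them, the
mask is relabeled, and the excluded percentage of patch area is reported.
The distance-to-snow-free surface is a Euclidean distance transform,
optionally after dropping patches below a minimum area (1,800 m² — two
coarse cells, the typical median patch size — keeps only median-sized or
larger targets).

## Selection statistics

The null model is proportional availability: expected on-patch positions =
N × (area of snow-free cells / total valid area). Selection is summarized
by the observed/expected ratio and by the odds ratio of the 2×2
used/available × on/off table with Wald CI on the log odds ratio
(z = 1.96); this interval reproduces published worked examples from their
printed counts exactly, which is why the Wald form was chosen. Expected
counts stay real-valued internally; rounding is display-only. A zero cell
makes Wald statistics undefined: the Haldane–Anscombe +0.5 correction is
applied only behind an explicit flag and the pipeline records when it was
used. Positions outside the mask extent are excluded and counted.

Diel windows: morning = [sunrise−1h, sunrise+1h), day = [sunrise+1h,
sunset−1h), evening = [sunset−1h, sunset+1h), night = remainder; all
half-open on the right, so the four windows tile each day exactly. Sunrise
and sunset come from the standard NOAA solar-geometry formulas (refraction
zenith 90.833°, UTC); dates without a sunrise or sunset raise a polar flag
and the positions are excluded from per-period statistics.

No step-selection or autocorrelation-aware inference is attempted: the null
is proportional availability, by design.

## RSPF models

Used cells come from GPS fixes snapped to the minimum-snow-depth fine cell
within a 5 m buffer (GPS error is a few meters and animals stand on the
local minimum more plausibly than on the nominal fix); ties go to the cell
nearest the fix, then row-major. Availability is a seeded uniform sample of
fine cells without replacement (default nine available rows per used row,
approximating the published design's ratio). Predictors are z-scored over
the pooled design with the sample (n−1) standard deviation; DEM² is squared
before standardization; constant columns raise an error naming the column.

Fitting is maximum-likelihood binary regression with the complementary
log-log response via IRLS (statsmodels GLM; tolerance 1e-8, max 100
iterations; rank-deficient designs and non-convergence raise). A weighted-
distribution RSPF estimator is deliberately not implemented; the plain
used/available GLM is the documented scope. AIC = 2k − 2 logL; rankings
flag models within 2 AIC units of the best. Hosmer–Lemeshow groups fitted
probabilities into deciles (df = groups − 2, which presumes the
probabilities were estimated; empty tied groups merge into a neighbor with
df adjusted). VIF_j = 1/(1 − R²_j) with an intercept in each auxiliary
regression.

## Synthetic study conditions

The generator emulates a scaled-down (600 × 600 m) tile of an alpine winter
range; every stage is a pure function of (seed, config) drawing from its own
child RNG stream.

* **Terrain**: spectral synthesis — white noise shaped by
  (1+k)^(−roughness/2), DC removed; roughness 3 (fractal-like), gain
  calibrated analytically so the surface sd is `terrain_relief` (40 m) at
  the default roughness. As roughness → ∞ every mode decays and the surface
  tends to a constant.
* **Snow**: depth = max(0, base + gain·(−TPI) + east_gradient·x + noise)
  with base 150 cm at the western edge, −100 cm/km eastward (domain mean
  ≈ 131 cm, a typical late-April plateau value), 5 cm of depth per meter of
  TPI, and noise (sd 15 cm) correlated over 10 m because snow depth does not
  vary independently square meter by square meter. Redistribution uses TPI
  at a 90 m window — wind acts at a broader scale than the 30 m analysis
  TPI, so ridges wider than one coarse cell can blow fully free. Under these
  defaults the coarse snow-free area at the 80/50/30 % thresholds is roughly
  1.5/15/35 % of the domain, the same ordering and magnitude as a real
  winter range.
* **NDSI scenes**: a monotone affine map of the snow-covered fraction
  (−0.15 bare to 0.85 full snow) plus independent scene noise (sd 0.08),
  clipped to [−1, 1]. Six scenes by default.
* **Lichen**: expected cover rises with the snow-free fraction (lichen
  heaths develop on wind-blown ridges), noisy, clipped to [0, 100] %.
* **Tracks**: a discrete-choice walk — per 3 h step, 10 isotropic Gaussian
  proposals (sd 200 m, a plausible winter 3-h displacement), reflected at
  the domain boundary (availability stays constant; no absorbing edges),
  chosen with probability ∝ exp(β·I[snow-free]). β = 0 is an unbiased
  random walk; the default β = 2 produces odds ratios of the same order as
  real winter selection. Four animals × 500 steps by default. The walk is an
  idealized stand-in: its β is a property of this choice mechanism, not a
  claim about any real animal, and real movement adds autocorrelation,
  herding and memory that the proportional-availability analysis does not
  model.

What passing tests on this generator show: the indices, calibration,
delineation and inference machinery recover known structure (signs,
orderings, coverage rates) under controlled noise. What they do not show:
performance on real imagery (cloud masks, sensor artifacts, mixed pixels),
real GPS error distributions, or behavioral processes beyond a memoryless
step preference.

## Numerical choices and degenerate inputs

* z for 95 % intervals is the exact normal quantile (1.95996…), not 1.96
  rounded, though the difference is far below reporting precision.
* Aggregation requires exact divisibility (no partial coarse blocks);
  reference cells straddling coverage edges are simply not reference cells.
* Thresholds are inclusive everywhere a published definition reads
  "X or more".
* All-nodata inputs yield nodata outputs rather than errors wherever a
  partial result is meaningful (mean scene, aggregation); operations whose
  result would be meaningless (empty calibration set, no position inside
  the mask, all-identical fitted probabilities) raise.
* Problem sizes in the default test and acceptance runs (600 m tiles,
  2,004 positions, 100 recovery replicates of n = 5,000, 50 null-selection
  replicates) were chosen as the smallest sizes at which the Monte-Carlo
  noise of each reported property is well below its decision band.

## Known limitations

* No reprojection/resampling; all layers must share one georeference.
* Estimation is the plain used/available GLM, not a weighted-distribution
  RSPF estimator; coefficient-level comparison with analyses fitted by
  other estimators is not claimed.
* The proportional-availability null ignores positional autocorrelation;
  with strongly autocorrelated tracks the Wald CI on the used side is
  anti-conservative.
* Patch connectivity (4 vs 8) changes patch counts; both are exposed and
  neither is asserted as "the" correct delineation rule.
* The synthetic lichen layer is a stand-in with a simple monotone link to
  snow-free fraction, not a vegetation model.
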