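# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `nh3ineq`. Everything quantitative below is either a
definition or a property the test suite and `scripts/acceptance.py` compute
at run time; no empirical claims are made beyond them.

## Observation model and oversampling

A sounding is a tuple (time, centre lat/lon, footprint semi-axes `a ≥ b`,
major-axis azimuth θ, column `C`, 1σ uncertainty `σ`, cloud fraction,
sensitivity flag, platform). Footprints are circular with a 12 km diameter
at nadir (`a = b = 6 km`) and elongate off-nadir; the simulator draws
`a = 6·(1+u) km`, `u ~ U(0,1)`, with uniform random azimuth.

The long-term mean column on a regular 0.01° grid is the inverse-variance
weighted mean over all quality-controlled soundings, with each sounding's
spatial influence given by the generalized-Gaussian response

    S(u, v) = exp(−ln2 · (|u/a|^k + |v/b|^k)),

evaluated at the cell centre's offset `(u, v)` in the footprint's rotated
frame. The half-max-at-edge convention (S = ½ exactly at the footprint edge
along each principal axis, i.e. FWHM = footprint diameter) makes the smooth
`k = 2` response and the sharp `k ≈ 18` physical response directly
comparable and gives an exactly testable anchor point. The per-cell value is

    V_j = Σ_i S_ij σ_i⁻² C_i / Σ_i S_ij σ_i⁻².

Numerical choices:

* Offsets are computed in km in the pixel's rotated local frame via
  equirectangular scaling at the pixel latitude (sub-metre error at
  footprint scale); point distances elsewhere use the haversine formula on
  a sphere of radius 6371.0088 km.
* Each pixel's support is truncated where `S <` 1e-4; the candidate cell
  box uses the conservative radius `hypot(a, b)·(ln(1e4)/ln2)^{1/k}` so no
  in-support cell is missed at any rotation. The truncation bounds cost and
  changes valid-cell values by less than the 1e-12 oracle tolerance used in
  the tests only because the oracle applies the same cutoff; its effect on
  the estimate itself is O(1e-4) of a single pixel's weight.
* Cells are evaluated at centres, not integrated over cell area: spacing
  (~1 km) is far below the narrowest footprint (12 km).
* A cell is valid when its accumulated weight reaches half the median
  inverse variance of the input pixels — "one typical pixel at half
  response". The rule is a package choice; the threshold is exposed.
* The QC postfilter retains soundings with `cloud_fraction ≤ 0.25` (config)
  and a true sensitivity flag. The 0.25 default is ours, standing in for a
  retrieval-recommended cloud/thermal-contrast filter whose exact
  thresholds live in the retrieval literature.

## Backgrounds and enhancements

The regional background for a period is a percentile (default the 10th) of
the valid-cell column distribution, computed with linear interpolation
between closest order statistics (tested against an independent
sort-and-interpolate oracle). Enhancements are `Δ = V − background` on
cells strictly above the background; cells at or below it are *flagged* and
excluded from aggregation rather than clipped to zero, so "block groups
with enhancements" means block groups with any enhanced coverage.

Two shared-reference conventions matter for stratified runs:

* strata reuse the **all-days background** of their parent period (each
  period still computes its own background);
* stratified distance profiles reuse the **all-days far-field noise level**
  (below). Both keep strata comparable: a stratum-specific reference would
  absorb part of the very signal being contrasted.

The percentile itself is selected by `select_background_decile`: for each
decile d ∈ {10, …, 90}, absolute inequalities are computed from raw columns
and from enhancements at background percentile d, and d is *equivalent*
when `|A_raw − A_Δ| ≤ z·√(SEM_raw² + SEM_Δ²)` for every group (z = 1.96 by
default; the equivalence criterion is a documented configuration, not a
claim about how such selections are always done). The procedure returns the
largest equivalent decile, falling back to 10 with a warning when none is.
A decile at which some group retains no enhanced block groups is counted as
non-equivalent. Higher deciles typically fail through a sampling effect:
low-column block groups that carry much of a group's population drop out of
the enhanced sample, so the group mean is recomputed over a different
population — the constructed counterexample in the tests makes this
mechanism explicit.

## Block-group aggregation and inequality metrics

Block-group values are area-weighted means over exact polygon–cell
intersections (shapely), with intersection areas converted to km² using the
cosine of the cell latitude; coverage is the enhanced-valid intersected
area over the polygon area. The containment-style approximations this
replaces (cell-centre-in-polygon) are avoided entirely; the residual
error from evaluating the cosine at cell rather than fragment latitude is
~1e-5 relative and is the tolerance used in the geometric oracle test.

For group g, eligibility selects block groups whose g-population *share* is
at or above the unweighted mean share across all block groups (a raw-count
variant is available by flag). Over the eligible, enhanced block groups:

    x̄_w = Σ p_i x_i / Σ p_i
    SEM  = sqrt( Σ w_i² (x_i − x̄_w)² ),  w_i = p_i / Σ p

The weighted SEM is our estimator (stated explicitly because weighted-mean
uncertainty conventions vary); it treats block-group values as independent,
which understates uncertainty where neighbouring block groups share
soundings — a known limitation. Inequality versus the reference group r is
`A = x̄_g − x̄_r` (absolute) and `100·A/x̄_r` (relative, undefined when
`x̄_r ≤ 0`), with `SEM_A = √(SEM_g² + SEM_r²)`. Absolute inequality is
invariant under adding a constant to all block-group values; relative is
not — both are asserted as properties.

The census-vintage decomposition recomputes each period's inequalities
under two demographic tables: differences across periods at fixed vintage
are column-driven; differences across vintages at fixed period are
composition-driven. Weights depend only on population shares up to a
uniform scaling, so uniformly scaled vintages are exactly equivalent.

## Meteorological stratification and distance analyses

Days are split at the median of morning (8 am–12 pm LT) station wind speed
or air temperature; days at the median go to the lower stratum (calm/cool).
A series with fewer than two distinct values is an error — the split is
undefined, not silently degenerate.

Block-group enhancements are profiled against the haversine distance from
the block-group centre point (polygon centroid; the data define no centre
points) to the nearest permitted swine facility, in half-open bins of
width 1 km by default. The far-field noise level is twice the standard
deviation of block-group enhancements at 15–20 km; the spatial extent is
the outer edge of the last bin in the contiguous-from-source run whose mean
is at least twice that noise level (SNR = 2). Empty bins terminate the
scan; a failing first bin gives extent 0. The contiguity rule is a
documented choice — non-contiguous exceedances farther out do not extend
the extent.

The pipeline's default bin width is 2 km rather than 1 km: the synthetic
block groups are ~5 km across, so block-group-level profiles cannot resolve
1-km bins (most would be empty). The 1-km default remains on
`distance_profile` itself for data that can support it.

## The synthetic scene generator

The generator emulates the statistical structure the analysis assumes, not
the physics that produces it.

* **Truth field**: `background + Σ_f strength_f · exp(−d_f/L)` — isotropic
  exponential decay per facility, additive across facilities. Defaults:
  background 3.8e15 molecules cm⁻² (the magnitude of the real regional
  background), source strengths U(5e15, 2e16) molecules cm⁻², decay length
  L = 5 km. L is set so that the 15–20 km noise band is genuinely far-field
  (truth there is e^−3 to e^−4 of source), the premise of the SNR=2 extent
  construct; it also matches profiles that decay to noise by ~10–15 km.
  This is a statistical stand-in: no plume physics, no wind direction, no
  deposition chemistry.
* **Facilities**: `n = 30` by default, drawn around 5 cluster centres with
  15 km Gaussian scatter, clipped to the 1°×1° region.
* **Block groups**: a 20×20 rectangular tessellation (~25 km² each,
  matching the ~20 km² regional average of real block groups).
* **Demographics**: non-reference shares follow a logistic link on
  standardized distance-to-nearest-facility, `share = 2·base·σ(bias·z)`,
  so `proximity_bias = 0` gives exactly the base shares everywhere (an
  exact null) and positive bias raises non-reference shares toward
  facilities. Base shares (0.25/0.10/0.02) use the study region's reported
  mean shares; `proximity_bias` defaults to 0.5. Block-group totals are
  lognormal (mean 1200, log-sd 0.5 — the block-group size range). Counts
  are deterministic expected counts (share × total, float): this keeps the
  zero-bias scene exactly symmetric across groups and the generator a pure
  function of (config, seed). All non-reference groups share the one link,
  so their designed gaps coincide; real groups differ, and per-group links
  would be a natural extension.
* **Meteorology**: wind lognormal with arithmetic mean 3 m s⁻¹ (log-sd
  0.5), temperature normal (24 ± 4 °C), precipitation exponential (mean
  0.14 mm) — the regional warm-season means. Zero spread produces
  identical days, on which a median split correctly fails.
* **Met modulation**: hot days (above median temperature) multiply source
  strengths by 1.5; calm days (at or below median wind — the same tie rule
  as the downstream split) multiply the decay length by 1.5. These give
  the stratified analyses a known truth: higher near-source enhancement on
  hot days, farther-reaching enhancement on calm days.
* **Soundings**: uniform random centres; columns are footprint-averaged
  truth (13-point unit-disk quadrature) times `1 + N(0, noise_cv)`;
  reported uncertainty is `noise_cv ×` the noise-free column (a fixed
  nominal value when `noise_cv = 0`, so equal weighting results); cloud
  fraction ~ Beta(0.8, 4) and sensitivity flags Bernoulli(0.9) give the
  postfilter realistic attrition (~30%).

### The designed-inequality oracle

`designed_inequality` is the relative/absolute inequality obtained by
pushing the *noise-free truth field as the estimator sees it* through the
standard downstream machinery (10th-percentile background, enhancement,
aggregation, population weighting). Kernel smoothing is part of the
estimator — the oversampled product is a footprint-and-response-convolved
image of the truth, and its inequalities differ from the pointwise field's
(the k = 2 vs k = 18 contrast shows the same thing on real data) — so a
recovery test must target the smoothed estimand or it fails at every
sampling density.

The dense-sampling limit is computed deterministically in two stages on the
analysis grid: the truth is convolved with the expected footprint-average
kernel (quadrature deposits averaged over elongations 0.25/0.75 and
azimuths 0°/45°/90°/135°), then regridded with the averaged response
kernel. Because uncertainties are proportional to the column, the
inverse-variance weighted limit at a cell is the ratio
`(S ∗ C⁻¹)/(S ∗ C⁻²)` over footprint-averaged columns `C` — a
harmonic-type mean slightly below the plain convolution wherever the field
varies within the response support — and the oracle computes exactly that
(a homoscedastic variant is available by flag). Remaining oracle
approximations: the discrete variant average versus the continuous
elongation/orientation distribution, and noise-versus-truth-based weights;
both are inside the recovery tolerance in the acceptance run.

Designed relative gaps on default scenes are large (hundreds of percent):
the compact tessellated region plus the share-above-mean eligibility rule
split near- and far-field block groups sharply, and far-field reference
enhancements are small. The synthetic scene is a recovery target with
controllable structure, not a calibrated replica of any real region — the
acceptance checks are property-based (null, recovery, directionality,
oracle equivalence), never magnitude comparisons against real-data values.

## Problem sizes

Default end-to-end runs use a 1°×1° region on a 100×100 grid, 400 block
groups, 30 facilities, 100–120 days × 120–150 soundings/day (12–18k
simulated; ~two-thirds survive QC), noise_cv = 0.15. The parameter-recovery
check uses ≥10,000 simulated soundings on a stationary scene (modulation
multipliers set to 1 so the designed oracle and the simulated truth
coincide); the stratification check uses the modulated defaults. A full
stratified run takes seconds on one CPU.

## What passing tests do and do not show

The generator reproduces the assumed structure: exponential decay,
uniform background, heteroscedastic multiplicative noise, overlapping
elliptical footprints, proximity-correlated demographics, met-modulated
truth. It does not reproduce: plume anisotropy and wind direction, spatially
varying backgrounds, correlated retrieval errors, irregular block-group
geometry, integer census counts and undercount, facility-size/type
heterogeneity, or seasonal cycles. Passing tests therefore demonstrate the
estimators' correctness and statistical behaviour under the stated model,
not the magnitude of real-world exposure inequalities.

## File formats

Pixels, demographics, facilities, meteorology and all stage outputs are
CSV; block groups are GeoJSON; backgrounds, scene truth and run reports are
JSON. Gridded products export as long-format CSV or as an
`xarray.Dataset` (`OversampledGrid.to_xarray()`) for NetCDF export through
whatever backend is installed.
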