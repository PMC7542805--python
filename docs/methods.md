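# Methods

`nichetrack` quantifies how consistently migratory animals occupy the same
*environmental* conditions across seasons — their Grinnellian niche — and
where the variation in that consistency sits: between individuals, between
populations, between years, or within them.  This note documents the models
and procedures, the parameters that matter, and the choices made where the
design was genuinely open.

## The niche model

For an analysis unit (one individual in one annual cycle, or one flyway's
pooled individuals in one annual cycle) and one season, the niche is the
density of the unit's occurrence points in environmental space, corrected
for what was available:

1. **Axes.** Temperature, precipitation and NDVI (a greenness proxy for
   food availability), used jointly (3-D) or singly (1-D).  No ordination is
   applied; the variables are used on their natural scales.
2. **Grid.** Each axis is divided into `R` equal-width bins spanning the
   min–max of the background annotation (defaults: `R = 100` in 1-D, `R =
   50` in 3-D).  Occurrence values outside the background range — possible
   in weather mode, where daily anomalies can exceed anything the background
   sample happened to draw — are clamped into the boundary bins and counted.
3. **Densities.** Occurrence and background points are smoothed with a
   product-Gaussian kernel evaluated at cell midpoints.  Per-axis bandwidths
   follow Silverman's d-dimensional rule on the respective input values,
   floored at half a bin width (below that floor the kernel can underflow
   between midpoints and a legitimately tight niche would register no mass).
   Densities are normalized to sum to 1 over the grid.
4. **Correction.** Corrected occupancy is `z ∝ z_occ / z_bkg` over the
   background's support, renormalized.  Support is defined as cells where
   the background density exceeds `10⁻³ / n_cells` (0.1% of the uniform cell
   mass).  A strictly positive floor is needed because the occurrence
   bandwidth (from ~10²–10³ points) is wider than the background bandwidth
   (from 10⁴ points), so the raw ratio grows without bound in the
   background's far tails and a single corner cell could otherwise dominate
   the corrected occupancy.  The floor is a parameter; the mass discarded
   outside support is reported.

Overlap between the corrected occupancies of two seasons is Schoener's

    D = 1 − ½ Σ_cells |z₁ − z₂| ∈ [0, 1].

## Weather and climate modes

Both modes share the same pipeline and differ only in annotation.
*Weather*: each occurrence point takes the daily layer of its own fix date;
each background point takes the daily layer of an independent random date
drawn uniformly over the season's days across the tracked years.
*Climate*: both occurrence and background points take the unweighted mean of
the season's two long-term monthly layers (the within-season aggregation is
an open choice; the unweighted mean is the simplest defensible one).
Grid lookups are nearest-cell, with no interpolation — bit-stable and
consistent with common raster extraction.

## Preprocessing

* **Daily subsampling** to at most 100 locations per day (uniform, without
  replacement) controls temporal autocorrelation and behavioural
  over-representation at high fix rates.
* **Seasons** are fixed two-month windows — spring Mar–Apr, summer Jun–Jul,
  autumn Sep–Oct, winter Dec–Jan — with one-month gaps absorbing
  phenological variation.  The annual cycle is anchored at summer:
  summer(Y) → autumn(Y) → winter(Y: Dec Y–Jan Y+1) → spring(Y: Mar–Apr
  Y+1), and the cycle closes with spring(Y) → summer(Y+1).  This makes every
  default season pair truly consecutive in time, including across New Year.
* **Full-year filter**: individuals tracked for less than one entire year
  (inclusive span < 365 days) or missing any season are excluded.
* **Spatial thinning** keeps one uniformly chosen location per occupied
  1-km cell, on a grid anchored at the environment origin so the result is
  stable under point reordering.

## Background (availability)

All of a flyway's locations, pooled across individuals, years and seasons,
define a 100% minimum convex polygon; the polygon is dilated by 300 km (the
maximum home-range scale of a large soaring migrant during staging and
wintering; configurable) and 10 000 points are sampled uniformly from the
result (clipped to the environment extent, so every point is annotatable).
One background per flyway serves all seasons — availability is meant to
describe what the flyway could reach over the whole year — with
season-specific annotation as above.

## The similarity (niche tracking) test

A unit *tracks* its niche between two seasons if observed overlap exceeds
what random use of the available environment would produce.  The null
redraws one season's occurrence environments uniformly (without
replacement) from that season's background annotation, corrects the
simulated density by the background exactly as the observed one, and
computes D against the other season's *observed* occupancy.  With `n_perm =
200` total randomizations (100 per direction), the unit is flagged as
tracking when observed D strictly exceeds the empirical 95th percentile of
the simulated values — one-sided, ties conservatively counted as
non-tracking.  An alternative null that translates the observed density
cloud by a random toroidal offset is available (`null="shift"`) for
sensitivity analysis; resampling is the default because the null hypothesis
is "environments used at random given availability", which resampling
embodies directly.

When both seasons' occurrences genuinely are uniform background draws, the
observed and simulated overlaps are exchangeable, so the test is calibrated
by construction; the acceptance suite verifies ~5% empirical rejection over
200 replicate null season pairs.

## Variance partitioning and repeatability

Variation in standardized overlap (Gaussian) and in the binary tracking
flag is partitioned with Bayesian random-intercept models

    y = Xβ + u_unit + v_year + ε,

fitted by a conjugate Gibbs sampler.  Fixed effects are intercept and
flyway.  Priors: residual variance ~ scaled-inverse-χ² with expectation
V = 1 and belief ν = 0.002; random-effect variances use a parameter-expanded
(redundant multiplicative) parameterization — u = α·η, α ~ N(0, 1000),
working variance ~ scaled-inv-χ²(V = 1, ν = 0.02) — giving a half-t-like
marginal that behaves well near zero variance.  Repeatability is

    R = V_B / (V_B + V_W),

with V_B the unit-intercept variance and V_W the residual; the year variance
V_Y is reported but kept out of the denominator so that R retains its
two-component meaning.  The binary model uses probit data augmentation
(latent Gaussian with residual variance fixed at 1); latent-scale
repeatability uses the link variance 1 as V_W (π²/3 can be supplied for a
logit-comparable scale).  A categorical/logit family would need a
non-conjugate sampler; the probit-augmentation choice is a deliberate,
documented deviation that keeps every update conjugate.

Default chains are 20 000 iterations, thinning 10, burn-in 2 000 (1 800
stored draws) — ample for these conjugate models at the data sizes involved;
`MCMCConfig.long()` provides the heavy 500 000 / 100 / 50 000 production
settings.  Lag-1 autocorrelations per stored parameter are reported and
flagged at |ac| ≥ 0.1 (not fatal; the intercept mixes slowly in small
balanced designs because it trades off against the random-intercept mean,
while the variance components — the quantities of interest — mix well).
With only two populations the between-population variance is weakly
identified; the model runs but warns.

Welch's unequal-variance t-test (with Welch–Satterthwaite df) serves the
scale and level contrasts (climate vs weather, individual vs population).

## The synthetic campaign

The generator emulates the study design, not the physiology of flight:

* **Environment.** Daily fields on a planar km grid (default 600 km square,
  10 km cells): smooth spatial gradient + seasonal cycle (constant within
  each season block) + spatially correlated daily noise (Gaussian-smoothed
  white noise, correlation length 5 cells; per-variable sd 2 °C, 1 mm/day,
  0.05 NDVI).  Monthly climate layers are computed as across-year means of
  the daily stack, so the climate/weather consistency invariant holds by
  construction and a zero-noise configuration collapses weather onto
  climate exactly.
* **Movement.** A biased correlated random walk per individual: each step's
  direction is a unit vector of (κ · descent direction of the environmental
  mismatch + standard-normal noise), with constant step length (default
  5 km per 20-min fix) and reflection at the domain boundary.  The mismatch
  is a variance-scaled squared distance between local conditions (weather
  or climate, configurable) and the individual's seasonal preferred values.
  κ = 0 is an environment-blind walk; κ ≈ 10 makes individuals sit on their
  preferred isolines.  Per-individual preference offsets
  (`individual_target_jitter`) create heterogeneous preferences centred on
  the flyway target.
* **Scale.** Default campaign: two flyways × five individuals × two years
  at 20-min fixes.  Experiments in the test suite use one-year, hourly-fix
  variants; these sizes keep full re-simulation cheap while preserving the
  multi-individual, multi-year, two-population structure the models need.
* **Reproducibility.** One global seed; every individual, stage and test
  derives a named substream by stable hashing, so results are independent
  of iteration order.

What the generator does *not* emulate — soaring flight, realistic flyway
geography, fix-quality dropout, geographic coordinates (it is planar; real
data must be projected to a metric CRS first) — bounds what passing tests
show: they certify the statistical machinery against known ground truth,
not the biology of any particular species.

## Numerical notes and limitations

* Environment grids are persisted as a compressed NPZ store with a JSON
  manifest (one array per variable per mode) rather than per-layer GeoTIFFs;
  the format is documented and round-trips exactly.
* Rejection sampling over the bounding box yields exactly-uniform polygon
  samples; degenerate polygons (zero area, collinear hulls) are rejected
  with explicit errors.
* Units with fewer than 5 points after thinning are skipped and logged, not
  imputed.
* D is clipped to [0, 1] against last-ulp float excursions.
* The pipeline's summary stage re-reads its own persisted CSVs before
  computing summaries, so every reported number is exactly recomputable from
  the intermediates on disk.
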