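# Methods

This note documents the statistical model behind `migvar`, the defaults
and why they are what they are, what the synthetic-data generator does
and does not emulate, and the numerical choices a maintainer would want
written down.

## Track preprocessing

Fixes are *(individual, UTC timestamp, lon, lat)*. All planar work uses a
spherical Lambert azimuthal equal-area projection (`migvar.geo`) centred
on the mean colony position; round-trip error is < 1 m and the equal-area
property — the only one the gridded estimators rely on — is exact. The
non-breeding season runs from **colony departure** (last detection within
10 km great-circle of the colony after the breeding period) to **colony
arrival** (first detection within 10 km before the next breeding period).
Because presence alone does not pin down "the breeding period", seasons
are anchored on a configurable window (default 1 May – 15 July) plus a
sustained-absence threshold (default 7 days): the season is the longest
≥7-day absence between consecutive anchor windows. This makes departure
well defined when birds make short pre-migration excursions; how
mid-season returns to the colony radius should be treated is genuinely
ambiguous and the longest-absence rule is our documented choice.

Inclusion filters: any season containing an inter-fix gap > 21 days is
dropped; individuals left with fewer than two seasons are dropped;
year-round residents are flagged and excluded. Filters are order-stable
and idempotent, and every drop is reported with its reason.

For seasonal UDs, fixes are thinned to one per 12-h bin (bins anchored at
the season's first fix). The fix nearest the **bin centre** is kept —
keeping the first fix of each bin would bias timing half a bin early —
and empty bins stay empty so that data holes remain visible.

## Utilization distributions and overlap

The seasonal UD is a bivariate normal kernel density on a 10-km
equal-area grid with fixed bandwidth h = 100 km, evaluated as the exact
per-cell Gaussian integral (separable normal CDF differences). The
density-at-centre × area approximation is available (`cell_mass="centre"`;
it agrees to < 1e−4 at h = 10 cell widths) but the exact integral is the
default since it is equally fast via a matrix product. The grid pads 3h
beyond the fix bounding box and masses are renormalized to sum to 1,
absorbing the ~0.3% of kernel mass beyond 3 standard deviations. Grid
origins snap to multiples of the cell size, so any two UDs with the same
cell size lie on one lattice and are aligned by exact zero-padding
(mass-preserving) before comparison.

The **k% isopleth** is the smallest cell set holding ≥ k of the mass
(cells added by decreasing mass; ties broken by row-major index). A
"95% UD" zeroes masses outside the 95% set **without renormalizing** —
this is forced by the convention that the Bhattacharyya affinity
BA = Σ√(p·q) of a 95% UD with itself is 0.95, the maximum attainable
overlap. BA is extent-sensitive at roughly the 1e−3 level through the
padding choice; the acceptance tolerance of ±0.002 on the self-overlap
reflects grid discretization, not an adjustable knob.

**Core areas** are the connected components (4-neighbour) of the 50%
isopleth. The **wintering area** is the core area with the most dwell
(counted in 12-h fixes = 0.5-day units) between 1 December and 31 March
inclusive; exact ties go to the area farther from the colony, consistent
with wintering areas typically being the farthest core area. Fragmented
winter polygons are grouped across years: when one year's winter polygon
intersects ≥ 2 of another year's 50% polygons those fragments are
unioned, repeated to a fixed point so the grouping is idempotent.
Point-in-area tests use the cell lattice (boundary-inclusive), which is
identical to polygon membership because polygons are unions of cells.
Winter arrival/departure are the first/last **full-rate** detections
inside the winter polygon. A transition bracketed by a gap longer than 3
days flags that date as missing (the affected trait only). An individual
**switches strategy** when any pair of its yearly winter polygons is
disjoint; switchers are excluded from distance regressions, individual
repeatability and the variation metrics, but retained in population
timing repeatability.

Migration distance is the great-circle distance (haversine, R = 6371 km)
from the colony to the mass-weighted centroid of the winter area; the
per-individual median across years is the distance covariate.

## Winter site fidelity (biased random bridge)

Winter fixes are used at full rate. Each step of duration T ≤ 3 h and
length ≥ 20 m contributes 10 time-interpolated kernels with variance
σ²(p) = h²_min + 4DTp(1−p), h_min = 150 m, weighted by T/10 so kernel
budget matches time spent, not fix count; steps shorter than 20 m are
treated as resting (σ = h_min); steps longer than 3 h contribute only
endpoint kernels (weight capped at 1.5 h each) so transmission gaps are
not bridged. The result is normalized on a 500-m grid. As D → 0 the
estimator reduces exactly to the fixed-kernel UD at h = h_min.

The diffusion coefficient default is a median-based plug-in:
D = median(L²/4T)/ln 2 over eligible steps. Under planar Brownian motion
L² is exponential with mean 4DT, so the raw median underestimates D by
ln 2; dividing it out gives a median-unbiased estimator that is still
robust to occasional ballistic commuting steps. This approximates, and is
not asserted equivalent to, the plug-in estimators bundled with existing
home-range software. Fidelity is the mean pairwise BA of the 95% winter
UDs on a common grid.

## Mean routes and route variation

Migration legs are the fixes from colony departure to winter arrival
(autumn) and winter departure to colony arrival (spring), with each
contiguous core-area visit replaced by one point at the area centroid so
routes consist of migratory flight only; a leg with a gap > 24 h outside
core areas is discarded (time inside a core area resets the clock).

The mean route of ≥ 2 same-direction legs is 500 points initialized as
the arc-length-uniform resampling of the pointwise leg average, then
iterated: each mean point moves to the centroid of its nearest locations
on each leg (continuous point-to-segment projection, robust to uneven fix
spacing), the polyline is re-spaced uniformly by arc length, and the
objective — mean over mean points of the mean squared nearest-neighbour
distance — is re-evaluated. A sweep that fails to decrease the objective
is rejected and iteration stops; otherwise it runs to a 1-km maximum
point displacement or 200 sweeps (non-convergence returns the best
iterate with a flag). The per-point variance is the mean squared distance
to each leg's nearest location (km²); **route variation** is the square
root of the mean per-point variance, so the headline statistic carries km
units (two legs offset ±d give exactly d). The mean-variance (km²) form
is exported alongside. Between-individual route variation applies the
same machinery to one leg from each of two paired individuals and is
symmetric in pair order.

## Variance partitioning and tests

Timing traits are expressed as days since 1 January of the season's
departure year (UTC), so winter departure around day 434 needs no year
wrap. Repeatability uses a REML linear mixed model: trait ~ migration
distance (fixed) + colony + individual (random intercepts; individuals
nest in colonies), fitted with statsmodels `MixedLM` (individual as a
variance component within colony groups; with a single colony the model
collapses to a plain random-intercept fit and colony variance is 0).
R = s²ₐ/(s²ₐ+s²ε) with s²ₐ the individual variance and s²ε the residual.
Year is deliberately not a random effect: year-to-year adjustment is
exactly the within-individual variation being measured. For the winter
arrival trait the distance fixed effect is dropped (a convergence
convention, exposed as the `include_distance` flag). 95% CIs come from a
parametric bootstrap (default 1,000 refits; failures are skipped and
counted).

Individual repeatability Rᵢ = s²ₐ/(s²ₐ+s²ᵢ) substitutes individual i's
own residual variance, s²ᵢ = Σe²ᵢⱼ/(nᵢ−1) over conditional residuals
e = s²ε V⁻¹(y − Xβ) computed per colony group with the estimated
variances (the (nᵢ−1) denominator is our choice; nothing canonical fixes
it). Individuals with one observation are skipped.

Between-individual comparisons pair individuals whose colonies **and**
winter centroids are both within 250 km, one randomly selected season per
individual per pair (seeded; pairs need not share years). The pair's
distance covariate is the mean of the two members' median distances. The
randomization test compares Δ = median(between) − median(within) against
10,000 label shuffles preserving group sizes, one-sided, with the add-one
estimate p = (1+#{Δ* ≥ Δ})/(n+1) — never exactly zero, and exact against
full enumeration on small inputs. Note that for a median statistic,
shuffles in which no element crosses either group median tie Δ exactly,
so even perfectly separated groups can sit a few counts above the 1/(n+1)
floor. Distance effects are OLS fits reported with the F statistic
against the intercept-only model (df 1, n−2); the equivalent likelihood
ratio test is computed alongside (they are monotone transforms for nested
Gaussian linear models). The between-individual regression serves as a
null model for the spatial constraint on short-distance migrants: its
prediction at each individual's distance is subtracted from the
within-individual value, and the corrected values are regressed on
distance again.

## Synthetic populations

The generator (`migvar.synthetic`) emulates the statistical structure the
analysis assumes, not gull behaviour: multi-year hourly fixes; colony
residence; outbound migration with 0–2 prolonged stopovers (≥ 21-day
dwell); winter residence 50–4,600 km from the colony (log-uniform, along
a configurable bearing sector so the 250-km pairing constraint can be
made satisfiable or not); return migration; device gaps on request.
Residences are stationary AR(1) walks (scale `site_jitter_km`, default
3 km); migration follows the great circle with a smooth lateral offset
(individual offset ~ N(0, 60 km) + yearly jitter ~ N(0, 25 km)) · sin(πf);
legs fly the first and last 250 km at 50 km/h cruise so radius crossings
are sharp, and spread any remaining slack over the middle of the leg.
Dates follow the two-level model: individual mean ~ N(population mean,
σ_among), yearly value ~ N(individual mean, σ_within); defaults
σ_among = 10 d, σ_within = 6 d (R_true ≈ 0.74, in the range typical of
avian timing repeatability), population means ~6 Aug / ~6 Oct / ~10 Mar /
~10 Apr. Clipping to keep the cycle ordered and travellable essentially
never binds at the default margins. Two dates are travel-linked rather
than independent draws — winter arrival of stopover-free individuals
(departure + flight time) and colony arrival of everyone (winter
departure + flight time) — and stopover use is an individual-level
property: both choices are forced jointly by realistic flight speeds and
the ground-truth contract R_true = σ²_among/(σ²_among+σ²_within) per
trait, since a direct migrant cannot spend 60 days covering 200 km
without manufacturing a spurious mid-route core area. Stopovers are
outbound-only, matching the empirical pattern that almost all staging
time precedes winter arrival.

What the generator does **not** emulate: wind and weather, foraging
decisions, solar-charging duty cycles, inter-annual winter-site switching
(switch detection is tested on constructed geometries), per-season
stopover skipping, and GPS error (±3 m is negligible at the analysis
scales). Passing tests therefore demonstrate that the estimators recover
a known generating process of the assumed structure — not that real gull
data satisfies those assumptions.

Two recovery properties tie the generator to the pipeline: colony
departure/arrival dates are recovered exactly to one fix interval on
gap-free tracks, and winter polygon entry/exit are detected within hours
(a kernel-smoothed 50% polygon extends ~100 km past the site, which a
bird at cruise speed crosses in 2–3 h; for sub-250-km migrants the winter
polygon necessarily includes the colony and "winter arrival" collapses
toward departure — an inherent property of the smoothed-polygon
definition, not an implementation artifact). Migration distance is
recovered within ~1 grid cell; repeatability of timing traits at 80
individuals × 3 years is recovered within ±0.1 of truth.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic populations
sized to keep statistical power while staying desk-scale: 80 × 3
individual-years for repeatability recovery, 2,000 simulated data sets at
999 permutations for randomization calibration, 8–10 individuals for
end-to-end pipeline checks, brute-force kernel oracles on ~50×50 grids.
Isopleth ties break row-major; UD normalization tolerance is 1e−9;
mean-route convergence is 1 km; permutation and bootstrap seeds are
explicit everywhere and a run's manifest records them.

## Known limitations

* The BRB diffusion plug-in is an approximation; BA-based fidelity is
  insensitive to modest mis-scaling of D but absolute UD shapes differ
  from other software.
* BA depends weakly (≲1e−3) on grid extent through padding; comparisons
  should use the package's own common-grid alignment.
* The mean-route iteration is a local optimizer; with strongly crossing
  or looping legs the nearest-neighbour map can settle in local minima.
  The objective monotonicity guarantee holds regardless.
* `MixedLM` variance components can hit the boundary (s²ₐ = 0) on small
  or degenerate data; results carry a `singular` flag and R is still
  reported from the returned components.
* Season splitting assumes one sustained absence per cycle; itinerant
  birds with multiple ≥7-day excursions keep only the longest.
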