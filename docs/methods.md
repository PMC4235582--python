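# Methods

`wolfroads` re-implements a complete summer wolf–road movement analysis as a
tested pipeline over synthetic data. This note documents the models, the
simulator that stands in for field data, the numerical choices, and what the
test suite does and does not demonstrate.

## The analysis chain

All coordinates are planar meters (a projected CRS is assumed upstream of
the pipeline); areas are reported in km², line densities in km/km².

### Positions → clusters and singles

GPS fixes are thinned to the hourly schedule (half-hourly collars keep the
on-the-hour fixes, ±5 min). Each position gets a 100 m buffer; overlapping
buffers are dissolved into **clusters**, which is equivalent to single-linkage
connected components at a 200 m center-to-center threshold (inclusive at
exactly 200 m — closed disks touch). Linkage ignores time, so revisits join
the same cluster. Size-1 components are **singles**.

Clusters are typed by hourly position count: ≥ 44 → den/rendezvous,
≤ 36 → bed, 37–43 → untyped and excluded from behavior-specific models
(the two published thresholds leave this gap; we exclude rather than invent
a rule). Den detection can additionally require a "star pattern" score —
the mean resultant length of bearings from the cluster centroid to the
positions reached by departing steps — to exceed a threshold; the default
threshold is 0, so the count criterion alone decides, because no operational
definition of the star pattern is available. Kill clusters cannot be
verified in the field here; a per-fix kill flag (from the simulator's
ground truth, or any user-supplied flag column) marks them.

Behavior at a position: Kill (kill-flagged cluster), Rest (bed cluster),
Travel (single).

### Travel speed

Steps between consecutive half-hourly fixes with dt ≤ 35 min and length
≥ 200 m give speeds in km/h. Each endpoint is on-road iff within 30 m of any
road (the GPS error scale); steps are `on` / `partly` / `off`. The model is
a Gaussian LMM, `speed ~ Road*Reproduction + Road*TimeOfDay +
Reproduction*TimeOfDay + Sex`, with random intercepts for territory and for
data set within territory, REML, backward elimination at α = 0.05 (Wald
tests; interactions leave before their main effects), and Nakagawa marginal /
conditional R². Reference cell: on-road, nonbreeding, Day. Day is
08:00–19:59, night 20:00–07:59. Speed steps are not filtered around
den/rendezvous clusters (the published filter set does not mention it).

### Step selection functions (site scale)

Hourly steps ≥ 200 m, excluding steps to or from den/rendezvous clusters,
are categorized SS/SC/CS/CC by their endpoint classes. Per category, the raw
samples of step length and turning angle form the empirical distributions
used to draw 10 matched random steps per real step (length and angle drawn
independently; joint sampling of the pair is not attempted). Random
endpoints outside the landscape are redrawn (≤ 100 attempts, then the
stratum is dropped). Endpoints are annotated with distances (km) to the
nearest gravel road, main road, and house, and with the land-cover class,
with water reassigned to the nearest terrestrial class.

Two model families, both conditional logistic (stratum softmax likelihood
maximized by damped Newton to gradient norm < 1e−8) with a
territory-clustered sandwich variance:

* **road-use**: on-gravel and on-main 30 m indicators only;
* **distance**: distances + centered quadratics + land-cover contrasts vs
  Forest, screened pairwise at |r| < 0.6 and backward-eliminated on robust
  Wald P-values.

Fitted overall and per time-of-day × behavior subset (subset membership by
the step's end time). Complete separation (e.g. a subset with no real step
on a main road) drives a coefficient toward ±∞; the fit stops at |β| > 15
and is flagged unstable rather than raising, mirroring the huge-magnitude
coefficients such subsets produce in standard software.

Validation is leave-one-territory-out: refit on the rest, score the held-out
strata, rank 1–11 within stratum (mid-ranks), sample one random row per
stratum (seeded), and run a one-sided paired Wilcoxon (exact for n ≤ 25
without ties, tie-corrected normal otherwise) of real ranks over sampled
random ranks; accept iff P ≤ 0.05.

### Resource selection functions (patch scale)

Used patches: every single position plus the earliest fix of each cluster,
as circles of radius 1.78 km. The radius is taken literally (area 9.95 km²);
the nominal "10 km²" is treated as rounding. Den/rendezvous and untyped
clusters yield used positions without a behavior label, so they enter no
behavior-specific model. Availability: 100 centers per data set, uniform
inside the 100% MCP of that data set's positions (rejection sampling;
centers, not whole circles, are constrained to the MCP, the weakest reading
of "within the home range" and the one that does not under-sample the MCP
margin). Patch covariates: gravel/main road density (exact analytic
segment–circle clipping), house density, land-cover fractions over grid
cells whose centers fall in the circle.

Models: random-intercept logistic regression (territory + data set within
territory) fitted by a Laplace approximation — an inner penalized Newton
solve for the fixed and random effects with the two variance components
profiled on the log scale by Nelder–Mead. Candidate terms: the screened
linear covariates plus quadratics for gravel density and mire fraction;
quadratics are centered on the covariate mean before squaring (numerical
conditioning). The collinearity screen keeps covariates in the priority
order gravel, houses, main roads, mire: houses and main roads are spatially
coupled in the simulator (and in the study region), and the patch-scale
human-disturbance signal is carried by houses, so houses win the tie.

Validation: 100× (configurable) repeated 10-fold cross-validation; each
validation fold is scored with training-fold coefficients, sorted, cut into
10 equal bins; Spearman r between bin rank and used-patch fraction; accept
iff the mean r ≥ 0.6.

### Functional response (home-range scale)

Per data set: availability = % of the home range's land (non-water) area
within 30 m of a gravel road (exact polygon union of per-segment buffers —
no double counting at junctions — clipped to the MCP, minus water);
use = % of hourly fixes within 30 m of a gravel road. Only water is
excluded from "land area". OLS of use on availability per reproductive
status with home-range size, median Julian date and sex as eliminable
covariates; the availability term is never eliminated because the test of
interest is H0: slope = 1 (t with n − p df), alongside H0: intercept = 0.
Percent, not proportion, is the regression scale. Proportional
(response-free) use corresponds to slope 1, intercept 0.

## The synthetic study

The simulator generates the *study conditions*, not a convenient test bed:
its defaults are the published study-area and data summaries.

**Landscape** (per territory): main roads as jittered grid crossings and
gravel roads as branching logging spurs rooted on main roads, both
length-controlled so realized density matches the target (defaults 0.19 and
0.88 km/km², the study means; per-territory targets vary around these, SD
0.06 and 0.20, reflecting the several-fold between-territory spread in the
published territory table). Houses: a Poisson cluster process with parents
biased to main-road neighborhoods, 3.0 per km². Land cover by quantile
thresholds on smoothed Gaussian noise: 81.7% forest, 10.5% mire, 4.6%
water, 3.2% open (the open class absorbs fields and built-up area).
Cell size 100 m — coarser than the 25–30 m source rasters, chosen to keep
grids tractable; land-cover covariates at the patch scale are insensitive
to this.

**Movement**: a discrete 30-min Markov chain over travel / bed / kill
handling / den attendance. Travel steps draw length from Gamma(shape 3,
mean 1075 m per half hour ≈ 2.15 km/h off-road) and turning angles from a
von Mises (κ = 4). With probability `road_attraction` (default 0.08) a
travel step snaps to the nearest road (main roads accepted at 0.35 of the
gravel rate), then follows the network — continuing across junctions onto
joining roads — with persistence 0.85 per step; on-road displacement is
`road_speed_multiplier` (default 1.8) × the drawn off-road length,
targeted on straight-line (chord) displacement so the speed contract holds
on curvy roads. Boundary encounters reflect both position and heading.
Bed/kill sites anchor ~40–400 m off the travel path (wolves step aside
before resting) and jitter tightly (30–40 m SD); kill handling dwells ~5 h,
beds ~2 h. Breeders commute to a den site (committed trips, producing the
radial star pattern and ≥ 44 hourly den fixes over a 21-day period) and
travel 1.2× faster. Night doubles the probability of entering travel.
Houses repel travel through a 3-candidate-heading choice weighted by
exp(−strength × houses within 1 km), default strength 0.3. Each scheduled
fix is kept with probability 0.81 (the published mean fix success).

A study bundles 10–14 territories with nested data sets (breeding fraction
8/14, half-hourly fraction 25/33, both from the published design), mixed
sexes and per-territory movement tempo (log-normal, SD 0.15). One master
seed drives a SeedSequence split per territory, data set and stage; the
whole bundle is byte-reproducible.

**What the simulator does not emulate**: GPS position error (fixes are
exact, so the 30 m threshold acts only as a corridor definition), terrain
and rivers, prey distribution and kill-site ecology, inter-pack dynamics,
seasonal drift in road use (the published analysis dropped Julian date, and
the simulator includes no seasonal term). Road attraction is a fixed
per-wolf probability, not a function of availability; the home-range-scale
use–availability relationship in the default study is therefore emergent
(denser networks keep road-following wolves on roads longer through
junction continuation) rather than prescribed, and the proportional-use
null for functional-response tests is obtained with `road_attraction = 0`. Passing tests therefore demonstrate that the
*estimators and procedures* behave correctly on data with the study's
statistical structure — not that they would reproduce the field results on
real trajectories.

A note on calibration: the published on/off speed ratio (1.8) is a measured
quantity under the same 30 m endpoint classification this pipeline uses.
Classification contaminates the `on` class with road-adjacent off-road
steps, so the measured ratio on simulated data runs slightly below the
mechanistic multiplier (≈ 1.65–1.75 at multiplier 1.8); the recovery tests
accept the 1.6–2.0 band for this reason.

## Numerical choices

* Conditional logistic: direct stratum-softmax Newton with step halving;
  identifiability requires within-stratum variation of every column;
  the clustered sandwich sums stratum scores within territories (with
  singleton clusters it reduces to HC0).
* Gaussian LMM: statsmodels `MixedLM` (REML). With one data set per
  territory the data-set component exactly duplicates the territory
  intercept and is dropped. Boundary fits (variance → 0) can leave the
  default optimizer with non-finite standard errors; such fits are retried
  with Nelder–Mead.
* Logistic GLMM: Laplace approximation, variance floors at e⁻²³, start at
  variance e⁻¹·⁵; against the degenerate-limit contract it matches plain
  logistic regression to < 1e−3. Quasi-separation (|β| > 10) is flagged.
* Wald P-values throughout, robust where a cluster term is declared;
  multi-column terms get joint Wald chi-square tests for elimination.
* Ties in rank validation are mid-ranked; a cross-validation bin with a
  constant used fraction contributes r = 0.
* Degenerate geometry raises typed errors (empty filtered network, all-water
  region, < 3 or collinear points for an MCP, out-of-extent lookups).

## Problem sizes

The analysis drivers and the acceptance script run a 10-territory /
24-data-set / 21-day study (≈ 17k fixes, ≈ 3k strata, ≈ 6k patches) with
3 cross-validation repetitions — a deliberately scaled-down replica of the
published 14-territory / 33-data-set design that preserves every structural
feature (nesting, mixed schedules, mixed status). The test suite uses
smaller bundles still. Simulation-based recovery tests use the sizes stated
in their docstrings (e.g. 500 strata, 30 territories × 2 × 200 for variance
components, ≥ 2000 travel steps for the speed ratio).

## Known limitations

* The random-step generator samples length and angle independently; if the
  two are strongly dependent in a category, matched availability is
  slightly misspecified (a joint-sampling flag is left as future work).
* The Laplace GLMM underestimates variance components for small clusters
  (as Laplace does); fixed effects are the quantities used downstream.
* Wilcoxon "V" statistics are comparable only within a model (their scale
  depends on the number of validation strata).
* The pipeline has no GPS-error screening and exactly one home-range
  estimator (100% MCP), by design.
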