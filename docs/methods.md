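# Methods

This note documents the models, algorithms and numerical choices behind
`climshift`, and what its synthetic study system does and does not emulate.

## Spatial frame and geodesy

All positions are WGS84 lat/lon.  Displacements between points use a local
equirectangular approximation on a sphere of radius R = 6371.0088 km:
north = R·Δφ, east = R·cos(φ̄)·Δλ.  For the regional separations that occur
here (< 1500 km at 55–70° N) this agrees with great-circle distances to well
under 1% (property-tested), and it is exactly invertible, which the hexagon
lattice relies on.  Compass bearings are 0° = north, clockwise, stored in
[0, 360); a zero-length displacement has no bearing and is flagged rather
than defaulted.

The hexagon grid is built in a Lambert cylindrical equal-area projection
centred on the study box, so each full flat-topped hexagon has exactly the
requested area (default 2165 km²) on the sphere; adjacent centres are
√(2A/√3) apart.  Cells are clipped to the box; clipped fragments smaller
than half a cell are merged into the neighbour sharing the longest border,
so the box is covered exactly, no cell is degenerate, and the cell count
tracks (box area)/(cell area).  Cells whose full hexagon lies inside the box
are flagged `interior`; only those are guaranteed the nominal area.
Hexagons belong to the province containing their centre; partial overlap is
not prorated (the underlying province data are too coarse to support it).

## Occupancy semantics

The occupancy cube is species × province × census boolean presence,
monotone along time: these are cumulative first records, and the package
deliberately has no extirpation pathway — sparse historical catalogues
cannot distinguish absence from non-detection, so richness is "species ever
recorded".  A (province, census) mask excludes unreliable combinations;
masked entries drop out of every aggregate, and a species' colonisation of a
masked province is dated to its first unmasked record (the alternative —
discarding the event — would silently deflate establishment counts).
Period durations are integer year differences (35, 51, 22, 10 under the
default censuses); rates divide by years or decades accordingly.

## Range shifts

A species' range front is the centroid of its northernmost occupied
province (latitude ties broken by smallest province id).  Northward velocity
per period is the northward displacement of that front divided by the period
length, floored at zero: cumulative occupancy cannot retreat, and small
negative values could only arise from centroid geometry of near-equal-
latitude provinces.  Species enter the velocity sample only once present at
a period's start, so sample sizes grow as species arrive.

Colonisation routes assume the shortest path: the source of each
colonisation event is the occupied province whose centroid is closest to
the colonised one (ties by id).  Candidates are the species' period-start
range; a species debuting within the period instead draws candidates from
its period-end range excluding the focal province, so a province never
sources itself, while debut species spreading across several provinces in
one period still receive routes.  A single-province debut has no route and
is logged, not fabricated.  Routes are averaged as circular means per
colonised province and period — one biological direction estimate per
province-period, mirroring one climatic estimate from the temperature side.

## Climate velocity

Annual cell temperatures are averaged into census values: the first census
uses the decade starting the year before it (1901 → 1900–1909), later
censuses use the last ten years of their period ([t−9, t]).  Because each
census value is a decadal mean, two consecutive censuses are effectively
separated by slightly less than their nominal year difference; velocities
derived through census means inherit that compression.  The recovery
analyses therefore feed the analogue algorithm single-year fields when a
known translation speed must be reproduced exactly.

The analogue algorithm per start cell: rank all cells (the start cell
included) by |temperature at period end − start temperature|, keep the best
`k_temp` (ties by ascending cell id); re-rank those by centroid distance,
keep `k_dist` (ties by id); average the displacement vectors componentwise.
Self-inclusion matters: an unchanged field then yields near-zero velocity
instead of a spurious jump to the nearest distinct cell.  Component
averaging (not angle averaging) preserves magnitude information.  The
selection is implemented with exact-tie partial sorts (O(n) memory per
cell) and is verified cell-for-cell against an exhaustive double-sort
reference on grids up to 200 cells.

Two systematic features deserve note.  (1) On noise-free fields with a
purely latitudinal gradient, temperature ties make the analogue band several
grid rows wide, and choosing the nearest `k_dist` biases the estimate about
half a band toward the start cell; the bias shrinks with grid density, which
is why velocity-recovery runs use 500 km² cells (≈ 3500 cells, bias < 5%).
(2) Cells near the trailing boundary lose their true analogue off-grid;
recovery statistics therefore evaluate interior cells only.

Province velocity is the mean north component of member-cell vectors per
year (it may be negative, i.e. southward); province direction is the
circular mean of member bearings, zero-magnitude vectors excluded.

## Circular statistics

Circular means use the resultant of unit vectors in compass convention;
a resultant below 1e−12 leaves the mean undefined (flagged NaN).  The
Watson–Williams two-sample test uses
F = K(N−2)(R₁+R₂−R)/(N−(R₁+R₂)) with K = 1 + 3/(8κ̂), κ̂ from the pooled
mean resultant length via the standard three-regime approximation
(r < 0.53: 2r + r³ + 5r⁵/6; r < 0.85: −0.4 + 1.39r + 0.43/(1−r); else
1/(r³ − 4r² + 3r)), and p from the upper tail of F(1, N−2).  The test
assumes reasonably concentrated von Mises samples; below pooled r̄ = 0.45 a
warning is emitted rather than a refusal, since the downstream pairing
logic, not the test, decides which provinces enter.  The "paired" design is
group construction only: each province contributes one biological and one
climatic angle, so 50 matched provinces give df (1, 98).

## Trait space and filtering tests

The trait space uses the four continuous traits (wingspan, European range
size in 50×50 km cells, STI mean, STI range), z-scored over the species
subset being compared, with Euclidean distances.  PERMANOVA's pseudo-F uses
the standard sums-of-squared-distance decomposition; permutations shuffle
group labels, restricted within strata when a province grouping is supplied
(the permutation analogue of treating province as a grouping factor — both
free and restricted permutation are exposed).  PERMDISP computes each
member's distance to its group centroid directly in the z-scored trait
space; for Euclidean distances this equals the principal-coordinate route
exactly (asserted in tests to 1e−8), avoiding negative-eigenvalue
corrections.  Its permutation null reassigns points to groups and recomputes
centroids and the ANOVA F.  Permutation p-values use (b+1)/(m+1), never
zero; a consequence worth knowing is that ties from partition-equivalent
relabelings count, so the attainable minimum at small equal group sizes is
larger than 1/(m+1).  Per-province scans run both tests for every province
with ≥ 2 original species and ≥ 2 colonisers and BH-adjust p-values across
provinces separately per test family (the two families answer different
questions; pooling them would couple their error budgets).

The dispersion–latitude analysis is ordinary least squares of per-province
mean dispersion on centroid latitude and province area, per group, plus a
combined fit with a group × latitude interaction; the interaction's Wald z
is the headline contrast.  Variable screening for the land-use models uses
single-linkage clustering on |Spearman ρ| with a 0.3 threshold; one
representative per cluster is kept, by caller preference order.

## Count and plateau models

Count responses (colonisations per province-period, new provinces per
species-period, initial occupancy) are zero-heavy and overdispersed, so
models are NB2 (variance μ + αμ²) with log link.  Fitting alternates a GLM
IRLS step for the coefficients at fixed α with a bounded profile-likelihood
update of log α, and asserts the joint log-likelihood never decreases;
agreement with a joint-MLE reference implementation is tested to 1e−3.
Random effects are replaced by fixed factors (period) or omitted (province):
at this data scale the province variance component is indistinguishable from
zero, so the fixed-effects approximation is exact for practical purposes;
spatially correlated mixed models are out of scope.  Term-level Wald χ²
tests cover multi-column factors.  The colonisation model takes land-use
shares at the period-start decade, z-scores all continuous predictors, uses
log(period decades) as offset, and reports the warming-rate optimum as the
vertex of the fitted quadratic mapped back to °C/decade (undefined when the
quadratic is convex).

The plateau curve y = plateau − (plateau − lower)·exp(−rate·x) is fitted by
nonlinear least squares from multiple starts (half-rise heuristic plus a
geometric rate grid); convergence is reported honestly, and a plateau
standard error exceeding the plateau itself flags weak identification —
the expected outcome when the data are effectively linear.

## The synthetic study system

`climshift.synth` emulates the frame of a century-scale Fennoscandian
butterfly atlas: 51 Voronoi provinces (scrambled-Halton seeds, mirrored
across the box edges so every cell is finite) spanning 55–70° N and
11–32° E; censuses 1901/1936/1987/2009/2019; 131 species; annual cell
temperature = 10 °C at the southern edge − 0.75 °C per degree latitude
+ 0.15 °C/decade warming + N(0, 0.3²) noise.  A translate mode instead
rigidly moves the 1900 field north at a configurable speed with zero noise,
as ground truth for velocity recovery.  All generators are pure functions of
the configuration; one master seed is split into fixed per-component
substreams.

Traits: diet breadth 25/35/40% mono/oligo/polyphagous; wingspan
LogNormal(log 35 mm, 0.25); STI mean N(8, 3) °C; STI range Gamma(mean 18,
shape 8) °C; habitat open/forest/generalist 45/25/30%; European range size
negative binomial with overall mean 1200 cells and a log-mean tied to
thermal-niche breadth (broad-niche species are also widespread — a
Rapoport-type association that links initial provincial occupancy to range
size, as the analyses assume).

Occupancy uses a one-sided, cold-limited thermal niche: a species
establishes in provinces at least as warm as its cold limit (STI mean minus
sti_range/3, floored at 1 °C) and is excluded from colder ones through a
soft 1 °C suitability edge.  This encodes a fauna at its poleward range
margin: what limits these species regionally is cold, not heat.  Initial
1901 ranges take the southernmost k of each species' feasible provinces,
with fill probability 0.72 × (residency) × (range-size factor), where
residency declines logistically with STI mean — cold-adapted species are
long-established and near-saturated, thermophiles are recent arrivals with
small footholds.  Colonisation per period is Bernoulli with
logit = β₀ + β_adj·[adjacent province occupied] + β_niche·suitability
(defaults −5.5, 2.0, 3.5), evaluated at period-end temperatures, with
province adjacency from shared Voronoi borders; occupancy never contracts.
An earlier symmetric-niche design (a temperature band around the STI mean
with a uniform southern start) was rejected because it inverts the intended
structure: it gives cold-adapted species the most unoccupied suitable
ground, so they — not thermophiles — expand most under warming.  Under the
cold-limited design, warming opens new provinces mainly to warm-adapted
species, and three structural properties hold across seeds: provincial
richness rises monotonically; initial occupancy correlates positively with
range size; and the top STI-mean quartile both gains more northern latitude
and shows a positive STI-mean slope in the establishment model.

A separate `northward` mode forces every species to colonise exactly its
nearest strictly-northern unoccupied province each period — deterministic
ground truth for direction recovery.

Land use: Dirichlet-initialised 1900 shares over open/cropland/forest/
grassland/settlement with deterministic decadal drifts (forest up, stronger
north; grassland down in the north; settlements up, stronger south),
renormalised to sum ≤ 1.

What the generator does **not** emulate: detection/effort variation (all
presences are true records), extirpations, abundance, spatially
heterogeneous warming (the trend is uniform, so the richness-versus-warming
plateau regression is weakly identified on synthetic data and is instead
validated on constructed saturating datasets), precipitation or seasonality,
immigration from outside the study box, and real province geometries.
Passing tests therefore demonstrate that the algorithms recover known
structure under the stated assumptions, not that the ecological conclusions
transfer to any particular real dataset.

## Problem sizes used in validation

Oracle equivalence uses grids ≤ 200 cells (20 random fields); velocity
recovery a ~3500-cell grid over a 50-year translation; direction recovery
five 100-province northward-mode histories; type-I calibration 1000–1500
replicates per test (199 permutations each) and 20 all-null province scans
at 999 permutations; model recovery 100 full study simulations for the
STI sign, 50 replicates of 200 province-periods for the warming-rate
optimum.  These sizes give Monte Carlo standard errors comfortably inside
the tolerances they are checked against.
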